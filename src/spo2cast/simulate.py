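"""Seeded synthetic ICU SpO2 cohort simulator.

Emulates the structure of pulse-oximetry monitoring records: a
near-saturated baseline (95-100%), transient desaturation events arriving
as a Poisson process with configurable depth and duration, additive
sensor noise, Bernoulli missingness, and either regular 5-minute or
irregular (thinned) sampling. Every stay carries its ground-truth event
intervals so downstream stages can be tested without restricted clinical
data. This is a test fixture generator, not a physiological gas-exchange
model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import RawStaySeries

__all__ = ["SyntheticCohortConfig", "generate_stay", "generate_cohort", "write_cohort_csv"]


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort.

    Distribution specs: ``stay_length_minutes`` is (min, mode, max) of a
    triangular distribution; ``event_depth_percent`` and
    ``event_duration_minutes`` are (low, high) of uniform distributions.
    ``subpopulations`` is an optional tuple of dicts, each with a
    ``label``, an ``n_stays``, and any config fields to override (e.g.
    different ``event_rate_per_hour`` for a ventilated-like group).
    """

    n_stays: int = 20
    stay_length_minutes: tuple = (330.0, 720.0, 1440.0)
    sampling_interval_minutes: float = 5.0
    event_rate_per_hour: float = 0.5
    event_depth_percent: tuple = (5.0, 25.0)
    event_duration_minutes: tuple = (15.0, 60.0)
    baseline_mean_percent: float = 97.0
    baseline_sd_percent: float = 1.0
    noise_sd_percent: float = 0.6
    missing_fraction: float = 0.05
    irregular: bool = False
    median_gap_minutes: float = 25.0
    event_shape: str = "exponential"
    cohort_label: str = "synthetic"
    subpopulations: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        if self.sampling_interval_minutes <= 0:
            raise ValueError("sampling_interval_minutes must be positive")
        if self.event_rate_per_hour < 0:
            raise ValueError("event_rate_per_hour must be nonnegative")
        if not 85.0 < self.baseline_mean_percent <= 100.0:
            raise ValueError("baseline_mean_percent must be in (85, 100]")
        if self.baseline_sd_percent < 0 or self.noise_sd_percent < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.median_gap_minutes <= 0:
            raise ValueError("median_gap_minutes must be positive")
        if self.event_shape not in ("exponential", "linear"):
            raise ValueError("event_shape must be 'exponential' or 'linear'")
        lo, mode, hi = self.stay_length_minutes
        if not lo <= mode <= hi or lo <= 0:
            raise ValueError("stay_length_minutes must satisfy 0 < min <= mode <= max")
        for name in ("event_depth_percent", "event_duration_minutes"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")


def _dip(times: np.ndarray, start: float, duration: float, depth: float, shape: str) -> np.ndarray:
    """Desaturation profile: descent then recovery over ``duration`` minutes.

    Exponential shape uses time constant duration/4 on each limb; linear
    shape is a triangle. Peak drop equals ``depth`` scaled by the limb
    value at mid-event for the exponential case (~0.86*depth).
    """
    rel = times - start
    half = duration / 2.0
    out = np.zeros_like(times)
    inside = (rel >= 0) & (rel <= duration)
    if shape == "linear":
        r = rel[inside]
        out[inside] = depth * np.where(r <= half, r / half, (duration - r) / half)
    else:
        tau = duration / 4.0
        r = rel[inside]
        peak = 1.0 - np.exp(-half / tau)  # value reached at mid-event
        desc = (1.0 - np.exp(-r / tau)) / peak
        rec = np.exp(-(r - half) / tau)
        out[inside] = depth * np.where(r <= half, desc, rec)
    return out


def _stay_rng(seed: int, stay_index: int) -> np.random.Generator:
    # one independent, reproducible stream per stay
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stay_index)]))


def generate_stay(
    config: SyntheticCohortConfig, stay_index: int, stay_id: str | None = None
) -> RawStaySeries:
    """Simulate one stay; deterministic in (config, stay_index)."""
    if stay_index < 0:
        raise ValueError("stay_index must be nonnegative")
    rng = _stay_rng(config.seed, stay_index)
    lo, mode, hi = config.stay_length_minutes
    length = float(rng.triangular(lo, mode, hi)) if lo < hi else float(lo)
    dt = config.sampling_interval_minutes
    times = dt * np.arange(int(np.floor(length / dt)) + 1)

    baseline = config.baseline_mean_percent
    if config.baseline_sd_percent > 0:
        baseline += config.baseline_sd_percent * rng.standard_normal()
    baseline = min(baseline, 100.0)

    values = np.full(times.shape, baseline)
    events = []
    n_events = rng.poisson(config.event_rate_per_hour * length / 60.0)
    for _ in range(n_events):
        start = rng.uniform(0.0, length)
        depth = rng.uniform(*config.event_depth_percent)
        duration = rng.uniform(*config.event_duration_minutes)
        values -= _dip(times, start, duration, depth, config.event_shape)
        events.append((start, min(start + duration, length)))
    events.sort()

    if config.noise_sd_percent > 0:
        values += config.noise_sd_percent * rng.standard_normal(times.shape)
    values = np.clip(values, 0.0, 100.0)

    if config.missing_fraction > 0:
        values[rng.random(times.shape) < config.missing_fraction] = np.nan

    if config.irregular:
        # thin the dense grid so inter-observation gaps are geometric with
        # median ~= median_gap_minutes; the first point anchors the stay
        q = 1.0 - 0.5 ** (dt / config.median_gap_minutes)
        keep = rng.random(times.shape) < q
        keep[0] = True
        times, values = times[keep], values[keep]

    return RawStaySeries(
        stay_id=stay_id if stay_id is not None else f"stay-{stay_index:04d}",
        times_minutes=times,
        spo2_percent=values,
        cohort_label=config.cohort_label,
        events=events,
    )


def generate_cohort(config: SyntheticCohortConfig):
    """Simulate a full cohort, optionally with labelled subpopulations.

    With ``subpopulations`` set, each entry contributes ``n_stays`` stays
    generated under the overridden config and tagged with its label;
    otherwise ``config.n_stays`` stays share ``config.cohort_label``.
    Stay ids are unique across the cohort and seeding is by global stay
    index, so the cohort is byte-identical across runs.
    """
    groups = config.subpopulations or (
        {"label": config.cohort_label, "n_stays": config.n_stays},
    )
    cohort = []
    index = 0
    for spec in groups:
        spec = dict(spec)
        label = spec.pop("label", config.cohort_label)
        n = int(spec.pop("n_stays", config.n_stays))
        sub = dataclasses.replace(
            config, cohort_label=label, subpopulations=(), n_stays=n, **spec
        )
        for _ in range(n):
            cohort.append(generate_stay(sub, index, stay_id=f"{label}-{index:04d}"))
            index += 1
    return cohort


def write_cohort_csv(cohort, path) -> None:
    """Write a cohort as tidy CSV with columns stay_id,time_min,spo2.

    Missing SpO2 values become empty fields. Cohort labels and
    ground-truth event annotations are in-memory metadata and are not
    serialized here; observation data round-trips losslessly through
    ``spo2cast.io.read_cohort_csv``.
    """
    frames = [
        pd.DataFrame(
            {"stay_id": s.stay_id, "time_min": s.times_minutes, "spo2": s.spo2_percent}
        )
        for s in cohort
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["stay_id", "time_min", "spo2"])
    )
    # 17 significant digits guarantee float64 round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")
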