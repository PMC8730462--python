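"""Preprocessing: SpO2 transform, regularization, smoothing, lag datasets.

The modeling space is p = 1 - exp((SpO2 - 100)/10), which maps 100% -> 0
and magnifies differences between saturation values near 100%. The
pipeline order is fixed: regularize to a 5-minute grid (forward fill,
leading backfill) -> transform -> causal moving-average smooth ->
optional downsample to 30 minutes -> supervised lag construction.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .series import RawStaySeries, SupervisedDataset, TransformedSeries

__all__ = [
    "P_MAX",
    "HYPOXEMIA_SPO2_THRESHOLD",
    "HYPOXEMIA_P_THRESHOLD",
    "transform_spo2",
    "inverse_transform",
    "SpO2Transformer",
    "regularize_series",
    "transform_series",
    "causal_smooth",
    "downsample",
    "apply_exclusions",
    "build_supervised",
    "concat_training",
    "prepare_series",
    "MIN_POINTS",
]

#: Image of [0, 100] under the transform: p in [0, 1 - e^-10].
P_MAX = 1.0 - math.exp(-10.0)

#: Hypoxemia threshold in percent; events are SpO2 strictly below this.
HYPOXEMIA_SPO2_THRESHOLD = 92.0

#: The same threshold in p space at full precision (prints as 0.55067).
HYPOXEMIA_P_THRESHOLD = 1.0 - math.exp(-0.8)

#: Minimum regular-grid points (5 hours at 5-minute sampling) to keep a stay.
MIN_POINTS = 61


def transform_spo2(spo2_percent):
    """Map SpO2 percent to p = 1 - exp((SpO2 - 100)/10).

    Strictly decreasing on [0, 100]; vectorized. Raises ``ValueError``
    outside the physical range.
    """
    s = np.asarray(spo2_percent, dtype=float)
    if np.any(np.isnan(s)) or s.size and (s.min() < 0.0 or s.max() > 100.0):
        raise ValueError("SpO2 values must be in [0, 100] and non-missing")
    p = 1.0 - np.exp((s - 100.0) / 10.0)
    return float(p) if np.isscalar(spo2_percent) else p


def inverse_transform(p):
    """Invert the transform: SpO2 = 100 + 10*ln(1 - p), for p in [0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(np.isnan(arr)) or arr.size and (arr.min() < 0.0 or arr.max() >= 1.0):
        raise ValueError("p must lie in [0, 1)")
    s = 100.0 + 10.0 * np.log1p(-arr)
    return float(s) if np.isscalar(p) else s


class SpO2Transformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer between percent and p space."""

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X):
        return transform_spo2(np.asarray(X, dtype=float))

    def inverse_transform(self, X):
        return inverse_transform(np.asarray(X, dtype=float))


def regularize_series(raw: RawStaySeries, interval_minutes: float = 5.0) -> RawStaySeries:
    """Resample a stay onto a uniform grid by forward fill.

    The grid runs from the first to the last observation time at
    ``interval_minutes`` steps, anchored at the first observation. Each
    grid point takes the most recent non-missing observation at or before
    it; grid points before the first valid observation are backfilled with
    the first available value. The output contains no missing values.
    """
    if raw.is_blank:
        raise ValueError(f"stay {raw.stay_id}: all SpO2 values missing")
    t = raw.times_minutes
    v = raw.spo2_percent
    valid = ~np.isnan(v)
    tv, vv = t[valid], v[valid]

    n_grid = int(np.floor((t[-1] - t[0]) / interval_minutes + 1e-9)) + 1
    grid = t[0] + interval_minutes * np.arange(n_grid)
    # index of last valid observation at or before each grid point
    idx = np.searchsorted(tv, grid + 1e-9) - 1
    backfill = idx < 0
    idx = np.clip(idx, 0, tv.size - 1)
    out = vv[idx]
    out[backfill] = vv[0]
    return RawStaySeries(
        stay_id=raw.stay_id,
        times_minutes=grid,
        spo2_percent=out,
        cohort_label=raw.cohort_label,
        events=list(raw.events),
    )


def transform_series(raw: RawStaySeries, interval_minutes: float = 5.0) -> TransformedSeries:
    """Transform a regularized stay to p space (no smoothing applied)."""
    return TransformedSeries(
        stay_id=raw.stay_id,
        interval_minutes=interval_minutes,
        p_values=transform_spo2(raw.spo2_percent),
        times_minutes=raw.times_minutes.copy(),
        smoothed=False,
        cohort_label=raw.cohort_label,
    )


def causal_smooth(
    series: TransformedSeries, window: int = 5, expanding_head: bool = False
) -> TransformedSeries:
    """Causal moving-average filter.

    output[i] = mean(input[i-window+1 .. i]) for i >= window-1. The first
    window-1 points pass through unsmoothed (the literal reading of the
    warm-up rule); with ``expanding_head=True`` they instead use an
    expanding mean over the available prefix. Output never depends on
    inputs after index i.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = series.p_values
    out = x.astype(float).copy()
    if x.size >= window:
        c = np.convolve(x, np.ones(window) / window, mode="valid")
        out[window - 1 :] = c
    head = min(window - 1, x.size)
    if expanding_head:
        out[:head] = np.cumsum(x[:head]) / (np.arange(head) + 1.0)
    return TransformedSeries(
        stay_id=series.stay_id,
        interval_minutes=series.interval_minutes,
        p_values=out,
        times_minutes=series.times_minutes.copy(),
        smoothed=True,
        cohort_label=series.cohort_label,
    )


def downsample(series: TransformedSeries, factor: int = 6) -> TransformedSeries:
    """Keep every ``factor``-th sample starting at index 0.

    With the default factor 6 a 5-minute series becomes a 30-minute
    series (the long-horizon model's input frequency).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return TransformedSeries(
        stay_id=series.stay_id,
        interval_minutes=series.interval_minutes * factor,
        p_values=series.p_values[::factor].copy(),
        times_minutes=series.times_minutes[::factor].copy(),
        smoothed=series.smoothed,
        cohort_label=series.cohort_label,
    )


def apply_exclusions(cohort, min_points: int = MIN_POINTS):
    """Partition stays into kept and dropped-with-reason.

    Stays whose SpO2 is entirely missing are dropped with reason
    ``"blank"``; stays with fewer than ``min_points`` points (5 hours of
    5-minute data by default, endpoints inclusive) are dropped with
    reason ``"too_short"``. Order is preserved.
    """
    kept, dropped = [], []
    for stay in cohort:
        if stay.is_blank:
            dropped.append((stay, "blank"))
        elif len(stay) < min_points:
            dropped.append((stay, "too_short"))
        else:
            kept.append(stay)
    return kept, dropped


def build_supervised(series: TransformedSeries, lags: int = 2) -> SupervisedDataset:
    """Rearrange a series into lag rows X and next-step targets Y.

    For values p_0..p_N, row t of X is (p_{t-L}, ..., p_{t-1}) and
    Y[t] = p_t for t = L..N, so the row count is len(series) - lags.
    A series with length <= lags yields an empty dataset with a warning.
    """
    if lags < 1:
        raise ValueError("lags must be >= 1")
    p = series.p_values
    n = p.size
    if n <= lags:
        warnings.warn(
            f"stay {series.stay_id}: length {n} <= lags {lags}; skipped",
            stacklevel=2,
        )
        return SupervisedDataset(
            lags=lags,
            X=np.empty((0, lags)),
            Y=np.empty(0),
            stay_boundaries=[(series.stay_id, 0, 0)],
        )
    X = np.column_stack([p[k : n - lags + k] for k in range(lags)])
    Y = p[lags:]
    return SupervisedDataset(
        lags=lags, X=X, Y=Y, stay_boundaries=[(series.stay_id, 0, n - lags)]
    )


def concat_training(datasets) -> SupervisedDataset:
    """Stack supervised datasets row-wise, preserving stay provenance.

    All inputs must share the same lag count; no X row ever mixes values
    from two stays because stacking happens after per-stay windowing.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    lags = datasets[0].lags
    if any(d.lags != lags for d in datasets):
        raise ValueError("all datasets must share the same lags")
    X = np.vstack([d.X for d in datasets])
    Y = np.concatenate([d.Y for d in datasets])
    boundaries, offset = [], 0
    for d in datasets:
        for sid, start, stop in d.stay_boundaries:
            boundaries.append((sid, start + offset, stop + offset))
        offset += d.n_rows
    return SupervisedDataset(lags=lags, X=X, Y=Y, stay_boundaries=boundaries)


def prepare_series(
    raw: RawStaySeries,
    horizon_minutes: float = 5.0,
    interval_minutes: float = 5.0,
    window: int = 5,
    expanding_head: bool = False,
) -> TransformedSeries:
    """Full per-stay preparation: regularize -> transform -> smooth -> downsample.

    Smoothing always happens at the base (5-minute) resolution; the
    30-minute horizon then keeps every 6th smoothed sample.
    """
    reg = regularize_series(raw, interval_minutes=interval_minutes)
    ts = causal_smooth(transform_series(reg, interval_minutes), window=window,
                       expanding_head=expanding_head)
    if horizon_minutes != interval_minutes:
        factor = horizon_minutes / interval_minutes
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("horizon must be a positive multiple of the interval")
        ts = downsample(ts, factor=int(round(factor)))
    return ts
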