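"""Shared data containers for per-stay SpO2 time series.

Times are minutes from the start of the ICU stay; missing SpO2
observations are carried as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawStaySeries", "TransformedSeries", "SupervisedDataset"]


@dataclass
class RawStaySeries:
    """One stay's raw (time, SpO2%) observations.

    Parameters
    ----------
    stay_id : str
        Unique identifier of the ICU stay.
    times_minutes : array
        Strictly increasing observation times in minutes from stay start.
    spo2_percent : array
        SpO2 in percent, same length as ``times_minutes``; NaN marks a
        missing observation. Non-missing values must lie in [0, 100].
    cohort_label : str
        Subpopulation tag (e.g. ``"ventilated"``); metadata only.
    events : list of (start, end)
        Ground-truth desaturation intervals in minutes, when known
        (populated by the synthetic simulator; empty for real data).
    """

    stay_id: str
    times_minutes: np.ndarray
    spo2_percent: np.ndarray
    cohort_label: str = "synthetic"
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_minutes = np.asarray(self.times_minutes, dtype=float)
        self.spo2_percent = np.asarray(self.spo2_percent, dtype=float)
        if self.times_minutes.shape != self.spo2_percent.shape:
            raise ValueError(
                f"stay {self.stay_id}: times and spo2 lengths differ "
                f"({self.times_minutes.size} vs {self.spo2_percent.size})"
            )
        if self.times_minutes.size > 1 and not np.all(np.diff(self.times_minutes) > 0):
            raise ValueError(f"stay {self.stay_id}: times must be strictly increasing")
        vals = self.spo2_percent[~np.isnan(self.spo2_percent)]
        if vals.size and (vals.min() < 0.0 or vals.max() > 100.0):
            raise ValueError(f"stay {self.stay_id}: SpO2 values outside [0, 100]")

    def __len__(self) -> int:
        return self.times_minutes.size

    @property
    def is_blank(self) -> bool:
        """True when every SpO2 observation is missing."""
        return bool(np.isnan(self.spo2_percent).all())


@dataclass
class TransformedSeries:
    """A regular-grid series in transformed (p) space, ready for modeling."""

    stay_id: str
    interval_minutes: float
    p_values: np.ndarray
    times_minutes: np.ndarray
    smoothed: bool = False
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.times_minutes = np.asarray(self.times_minutes, dtype=float)
        if self.p_values.shape != self.times_minutes.shape:
            raise ValueError(f"stay {self.stay_id}: p/time length mismatch")

    def __len__(self) -> int:
        return self.p_values.size


@dataclass
class SupervisedDataset:
    """Lag matrix X and next-step target Y for one-step-ahead regression.

    ``stay_boundaries`` maps each stay to its half-open row range
    ``(stay_id, start, stop)`` so pooled rows keep their provenance.
    """

    lags: int
    X: np.ndarray
    Y: np.ndarray
    stay_boundaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(-1, self.lags)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X row count must equal length of Y")

    @property
    def n_rows(self) -> int:
        return self.Y.size

    def __len__(self) -> int:
        return self.Y.size
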