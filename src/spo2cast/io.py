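"""Reading and writing the tidy cohort CSV format.

Columns are ``stay_id,time_min,spo2``; an empty spo2 field marks a
missing observation. Times are minutes from stay start.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .series import RawStaySeries

__all__ = ["read_cohort_csv"]

_COLUMNS = ["stay_id", "time_min", "spo2"]


def read_cohort_csv(path, default_label: str = "synthetic"):
    """Parse a cohort CSV into per-stay series.

    Rows are grouped by ``stay_id`` in order of first appearance; rows
    within a stay are sorted by time (with a warning if they arrived
    unsorted). Values outside [0, 100] raise a validation error naming
    the offending line.
    """
    try:
        # round_trip parsing keeps 17-digit floats bit-exact on re-read
        df = pd.read_csv(path, dtype={"stay_id": str}, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"{path}: malformed cohort CSV: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    for col in ("time_min", "spo2"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
    bad = df.index[(df["spo2"] < 0) | (df["spo2"] > 100)]
    if len(bad):
        line = int(bad[0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"{path}: SpO2 value {df.loc[bad[0], 'spo2']} outside [0, 100] at line {line}"
        )
    if df["time_min"].isna().any():
        line = int(df.index[df["time_min"].isna()][0]) + 2
        raise ValueError(f"{path}: missing time_min at line {line}")

    cohort = []
    for stay_id, group in df.groupby("stay_id", sort=False):
        times = group["time_min"].to_numpy(dtype=float)
        values = group["spo2"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            warnings.warn(f"stay {stay_id}: unsorted times; sorting", stacklevel=2)
            order = np.argsort(times, kind="stable")
            times, values = times[order], values[order]
        if np.any(np.diff(times) == 0):
            raise ValueError(f"{path}: duplicate timestamps in stay {stay_id}")
        cohort.append(
            RawStaySeries(
                stay_id=str(stay_id),
                times_minutes=times,
                spo2_percent=values,
                cohort_label=default_label,
            )
        )
    return cohort
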