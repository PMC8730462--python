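"""Hypoxemia event classification and per-stay / pooled evaluation.

Forecasts are thresholded at SpO2 92% (transformed p = 1 - e^-0.8,
printed as 0.55067): a timepoint is a hypoxemic event when saturation
falls strictly below the threshold. Per-stay metrics follow explicit
undefined-value semantics — sensitivity is undefined for stays with no
true events, specificity for stays that are entirely events, PPV for
stays with no positive predictions, and Pearson's r for constant
series — and undefined values propagate as ``None``, never as 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import HYPOXEMIA_P_THRESHOLD
from .series import TransformedSeries

__all__ = [
    "StayPrediction",
    "StayMetrics",
    "AggregateResults",
    "classify_hypoxemia",
    "make_stay_prediction",
    "stay_metrics",
    "aggregate_confusion",
    "summarize_cohort",
    "sensitivity_subgroup_test",
    "ventilation_chisq",
]


def classify_hypoxemia(p_series, threshold: float = HYPOXEMIA_P_THRESHOLD,
                       inclusive: bool = False) -> np.ndarray:
    """Label each transformed value as hypoxemic (True) or not.

    A point is hypoxemic iff p > threshold, i.e. SpO2 strictly below 92%;
    a reading exactly at 92% is non-hypoxemic (set ``inclusive=True`` to
    flip the boundary rule).
    """
    p = np.asarray(p_series, dtype=float)
    return p >= threshold if inclusive else p > threshold


@dataclass
class StayPrediction:
    """Aligned true/predicted p-series and event labels for one stay."""

    stay_id: str
    times_minutes: np.ndarray
    p_true: np.ndarray
    p_pred: np.ndarray
    label_true: np.ndarray = field(default=None)
    label_pred: np.ndarray = field(default=None)
    cohort_label: str = "synthetic"

    def __post_init__(self):
        self.p_true = np.asarray(self.p_true, dtype=float)
        self.p_pred = np.asarray(self.p_pred, dtype=float)
        self.times_minutes = np.asarray(self.times_minutes, dtype=float)
        if self.label_true is None:
            self.label_true = classify_hypoxemia(self.p_true)
        if self.label_pred is None:
            self.label_pred = classify_hypoxemia(self.p_pred)
        lengths = {
            self.times_minutes.size, self.p_true.size, self.p_pred.size,
            np.asarray(self.label_true).size, np.asarray(self.label_pred).size,
        }
        if len(lengths) != 1:
            raise ValueError(f"stay {self.stay_id}: misaligned prediction vectors")

    def __len__(self):
        return self.p_true.size


def make_stay_prediction(series: TransformedSeries, p_pred, lags: int = 2) -> StayPrediction:
    """Pair a preprocessed stay with its forecast (aligned to lags..end)."""
    p_pred = np.asarray(p_pred, dtype=float)
    return StayPrediction(
        stay_id=series.stay_id,
        times_minutes=series.times_minutes[lags:],
        p_true=series.p_values[lags:],
        p_pred=p_pred,
        cohort_label=series.cohort_label,
    )


@dataclass
class StayMetrics:
    """Per-stay classification and waveform metrics.

    ``sensitivity``, ``specificity``, ``ppv`` and ``pearson_r`` are
    ``None`` exactly when their defining denominator is empty (no true
    events / no true non-events / no positive predictions / a constant
    series).
    """

    stay_id: str
    counts: tuple  # (TP, FP, TN, FN)
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    mse: float
    pearson_r: float | None
    n_true_events: int = 0
    cohort_label: str = "synthetic"


def stay_metrics(pred: StayPrediction) -> StayMetrics:
    """Confusion counts and waveform fit for one stay's forecast."""
    if len(pred) == 0:
        raise ValueError(f"stay {pred.stay_id}: empty prediction")
    t = np.asarray(pred.label_true, dtype=bool)
    p = np.asarray(pred.label_pred, dtype=bool)
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    mse = float(np.mean((pred.p_true - pred.p_pred) ** 2))
    if np.ptp(pred.p_true) == 0.0 or np.ptp(pred.p_pred) == 0.0:
        r = None  # correlation with a constant series is undefined
    else:
        r = float(stats.pearsonr(pred.p_true, pred.p_pred).statistic)
    return StayMetrics(
        stay_id=pred.stay_id,
        counts=(tp, fp, tn, fn),
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        mse=mse,
        pearson_r=r,
        n_true_events=tp + fn,
        cohort_label=pred.cohort_label,
    )


@dataclass
class AggregateResults:
    """Pooled confusion counts and rates over all timepoints of all stays."""

    counts: tuple  # (TP, FP, TN, FN)
    false_positive_rate: float | None
    false_negative_rate: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    accuracy: float


def aggregate_confusion(stays) -> AggregateResults:
    """Sum per-stay counts and derive pooled rates.

    FPR = FP/(FP+TN), FNR = FN/(FN+TP); pooled sensitivity, specificity,
    PPV and accuracy come from the summed counts (equivalent to flattening
    every stay's label stream and counting once).
    """
    stays = list(stays)
    if not stays:
        raise ValueError("no stays to aggregate")
    tp = sum(m.counts[0] for m in stays)
    fp = sum(m.counts[1] for m in stays)
    tn = sum(m.counts[2] for m in stays)
    fn = sum(m.counts[3] for m in stays)
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return AggregateResults(
        counts=(tp, fp, tn, fn),
        false_positive_rate=fp / (fp + tn) if fp + tn > 0 else None,
        false_negative_rate=fn / (fn + tp) if fn + tp > 0 else None,
        sensitivity=tp / (tp + fn) if tp + fn > 0 else None,
        specificity=tn / (tn + fp) if tn + fp > 0 else None,
        ppv=tp / (tp + fp) if tp + fp > 0 else None,
        accuracy=(tp + tn) / total,
    )


_METRIC_FIELDS = ("accuracy", "sensitivity", "specificity", "ppv", "mse", "pearson_r")


def summarize_cohort(stays, metrics=_METRIC_FIELDS) -> dict:
    """Box-plot style distribution summary of per-stay metrics.

    For each metric: mean, median, Q1, Q3 (linear-interpolation
    quantiles), Tukey whisker values (most extreme data point within
    1.5*IQR of the box), the fence bounds, outliers beyond the fences,
    and the count of stays excluded because the metric was undefined.
    """
    stays = list(stays)
    if not stays:
        raise ValueError("no stays to summarize")
    out = {}
    for name in metrics:
        values = np.array(
            [getattr(m, name) for m in stays if getattr(m, name) is not None],
            dtype=float,
        )
        n_undefined = len(stays) - values.size
        if values.size == 0:
            out[name] = {"n": 0, "n_undefined": n_undefined}
            continue
        q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = values[(values >= lo_fence) & (values <= hi_fence)]
        out[name] = {
            "n": int(values.size),
            "n_undefined": int(n_undefined),
            "mean": float(values.mean()),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "lower_fence": float(lo_fence),
            "upper_fence": float(hi_fence),
            "lower_whisker": float(inside.min()),
            "upper_whisker": float(inside.max()),
            "outliers": sorted(float(v) for v in values[(values < lo_fence) | (values > hi_fence)]),
        }
    return out


def sensitivity_subgroup_test(stays, event_counts=None, cutoff: float = 0.5) -> dict:
    """Compare hypoxemic-event counts between low- and high-sensitivity stays.

    Restricted to stays where sensitivity is defined, the stays split at
    ``sensitivity < cutoff`` vs ``>= cutoff``; Welch's unequal-variance
    t-test then compares the mean number of true hypoxemic events between
    the two subgroups, alongside subgroup medians. ``event_counts`` maps
    stay_id to the event count (defaults to each stay's own
    ``n_true_events``).
    """
    stays = [m for m in list(stays) if m.sensitivity is not None]

    def _count(m):
        if event_counts is None:
            return m.n_true_events
        return event_counts[m.stay_id]

    low = np.array([_count(m) for m in stays if m.sensitivity < cutoff], dtype=float)
    high = np.array([_count(m) for m in stays if m.sensitivity >= cutoff], dtype=float)
    report = {
        "cutoff": cutoff,
        "n_low": int(low.size),
        "n_high": int(high.size),
        "median_low": float(np.median(low)) if low.size else None,
        "median_high": float(np.median(high)) if high.size else None,
        "mean_low": float(low.mean()) if low.size else None,
        "mean_high": float(high.mean()) if high.size else None,
    }
    if low.size < 2 or high.size < 2:
        report.update(
            computable=False,
            reason="each subgroup needs >= 2 stays with defined sensitivity",
            t_statistic=None,
            p_value=None,
        )
        return report
    if np.ptp(low) == 0 and np.ptp(high) == 0 and low.mean() == high.mean():
        # identical constant groups: zero effect by definition
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_ind(low, high, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    report.update(computable=True, t_statistic=t_stat, p_value=p_val)
    return report


def ventilation_chisq(contingency) -> dict:
    """Pearson chi-squared test of independence on a 2x2 table.

    Rows are cohort labels (e.g. ventilated vs not), columns hypoxemic vs
    non-hypoxemic timepoint counts. No Yates continuity correction, so
    the statistic equals the textbook sum of (O-E)^2/E with df = 1.
    """
    table = np.asarray(contingency, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total; test undefined")
    res = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "df": int(res.dof),
        "expected": res.expected_freq.tolist(),
    }
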