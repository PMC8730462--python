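"""Event classification, per-stay metrics, pooling, subgroup statistics."""

import numpy as np
import pytest

from spo2cast import (
    HYPOXEMIA_P_THRESHOLD,
    StayPrediction,
    aggregate_confusion,
    classify_hypoxemia,
    sensitivity_subgroup_test,
    stay_metrics,
    summarize_cohort,
    transform_spo2,
    ventilation_chisq,
)

# frozen closed-form oracles (computed independently with sympy):
WELCH_T_SMALL = -10.3173884769058  # groups {0,0,1} vs {50,60,70}
CHI2_TABLE = 800.0 / 21.0          # table [[10,90],[50,50]], sum (O-E)^2/E


def prediction(p_true, p_pred, stay_id="s", label="synthetic"):
    p_true = np.asarray(p_true, dtype=float)
    return StayPrediction(
        stay_id=stay_id,
        times_minutes=5.0 * np.arange(p_true.size),
        p_true=p_true,
        p_pred=np.asarray(p_pred, dtype=float),
        cohort_label=label,
    )


def from_labels(truth, pred, **kw):
    """Build a StayPrediction whose labels match given boolean streams."""
    lo, hi = 0.7, 0.3  # p above / below the threshold
    return prediction([lo if t else hi for t in truth],
                      [lo if p else hi for p in pred], **kw)


class TestClassify:
    def test_percent_values_threshold_strictly_below_92(self):
        p = transform_spo2(np.array([95.0, 92.0, 91.0, 75.0]))
        np.testing.assert_array_equal(
            classify_hypoxemia(p), [False, False, True, True]
        )

    def test_full_saturation_never_hypoxemic(self):
        assert not classify_hypoxemia(transform_spo2(np.full(10, 100.0))).any()

    def test_labeling_equivalent_in_percent_and_p_space(self):
        rng = np.random.default_rng(3)
        spo2 = rng.uniform(60.0, 100.0, 10_000)
        np.testing.assert_array_equal(
            classify_hypoxemia(transform_spo2(spo2)), spo2 < 92.0
        )

    def test_inclusive_boundary_option(self):
        p = transform_spo2(np.array([92.0]))
        assert not classify_hypoxemia(p)[0]
        assert classify_hypoxemia(p, inclusive=True)[0]


class TestStayMetrics:
    def test_hand_counted_example(self):
        m = stay_metrics(from_labels([1, 1, 0, 0], [1, 0, 0, 0]))
        assert m.counts == (1, 0, 2, 1)
        assert m.sensitivity == 0.5
        assert m.specificity == 1.0
        assert m.ppv == 1.0
        assert m.accuracy == 0.75

    def test_undefined_sensitivity_and_ppv_when_no_events_predicted_or_true(self):
        m = stay_metrics(from_labels([0, 0, 0], [0, 0, 0]))
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.specificity == 1.0

    def test_undefined_specificity_when_all_events(self):
        m = stay_metrics(from_labels([1, 1, 1], [1, 0, 1]))
        assert m.specificity is None
        assert m.sensitivity == pytest.approx(2 / 3)

    def test_constant_true_series_has_undefined_pearson(self):
        m = stay_metrics(prediction([0.3, 0.3, 0.3], [0.31, 0.29, 0.30]))
        assert m.pearson_r is None

    def test_perfect_forecast_limit(self):
        p = np.array([0.2, 0.7, 0.4, 0.6, 0.3])
        m = stay_metrics(prediction(p, p))
        assert m.accuracy == 1.0
        assert m.mse == 0.0
        assert m.pearson_r == pytest.approx(1.0)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        m = stay_metrics(prediction(rng.uniform(0, 0.99, 57), rng.uniform(0, 0.99, 57)))
        assert sum(m.counts) == 57

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            stay_metrics(prediction([], []))


class TestAggregate:
    def test_counts_are_additive(self):
        stays = [
            stay_metrics(from_labels([1, 0, 0, 0], [1, 0, 0, 0], stay_id="a")),
            stay_metrics(from_labels([1, 0, 0, 1], [0, 1, 0, 0], stay_id="b")),
        ]
        agg = aggregate_confusion(stays)
        expected = tuple(
            sum(m.counts[i] for m in stays) for i in range(4)
        )
        assert agg.counts == expected

    def test_single_stay_pooled_equals_stay_metrics(self):
        m = stay_metrics(from_labels([1, 1, 0, 0], [1, 0, 0, 0]))
        agg = aggregate_confusion([m])
        assert agg.sensitivity == m.sensitivity
        assert agg.specificity == m.specificity
        assert agg.ppv == m.ppv
        assert agg.accuracy == m.accuracy

    def test_pooled_rates_match_flattened_label_stream(self):
        rng = np.random.default_rng(7)
        truths, preds, stays = [], [], []
        for k in range(12):
            t = rng.random(rng.integers(5, 40)) < 0.3
            p = rng.random(t.size) < 0.3
            truths.append(t)
            preds.append(p)
            stays.append(stay_metrics(from_labels(t, p, stay_id=str(k))))
        agg = aggregate_confusion(stays)
        t = np.concatenate(truths)
        p = np.concatenate(preds)
        # brute-force flatten-and-count oracle
        assert agg.counts == (
            int(np.sum(t & p)), int(np.sum(~t & p)),
            int(np.sum(~t & ~p)), int(np.sum(t & ~p)),
        )
        assert agg.false_positive_rate == pytest.approx(
            np.sum(~t & p) / np.sum(~t)
        )
        assert agg.false_negative_rate == pytest.approx(
            np.sum(t & ~p) / np.sum(t)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_confusion([])


class TestSummaries:
    def test_identical_metrics_collapse_quartiles(self):
        stays = [stay_metrics(from_labels([1, 0], [1, 0], stay_id=str(i)))
                 for i in range(5)]
        s = summarize_cohort(stays, metrics=("accuracy",))["accuracy"]
        assert s["q1"] == s["median"] == s["q3"] == 1.0

    def test_mean_of_zero_and_one(self):
        a = stay_metrics(from_labels([1, 0], [1, 0], stay_id="good"))
        b = stay_metrics(from_labels([1, 0], [0, 1], stay_id="bad"))
        s = summarize_cohort([a, b], metrics=("accuracy",))["accuracy"]
        assert s["mean"] == 0.5

    def test_whiskers_match_quantile_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0.8, 0.1, 101)

        class Fake:
            def __init__(self, v):
                self.accuracy = float(v)

        s = summarize_cohort([Fake(v) for v in values], metrics=("accuracy",))[
            "accuracy"
        ]
        q1, q3 = np.percentile(values, [25, 75])
        hi_fence = q3 + 1.5 * (q3 - q1)
        lo_fence = q1 - 1.5 * (q3 - q1)
        assert s["upper_fence"] == pytest.approx(hi_fence)
        assert s["upper_whisker"] == values[values <= hi_fence].max()
        assert s["lower_whisker"] == values[values >= lo_fence].min()
        assert s["n_undefined"] == 0

    def test_undefined_values_excluded_with_count(self):
        a = stay_metrics(from_labels([0, 0], [0, 0], stay_id="quiet"))  # sens None
        b = stay_metrics(from_labels([1, 0], [1, 0], stay_id="event"))
        s = summarize_cohort([a, b], metrics=("sensitivity",))["sensitivity"]
        assert s["n"] == 1 and s["n_undefined"] == 1
        assert s["mean"] == 1.0


class _M:
    """Minimal stand-in carrying only what the subgroup test reads."""

    def __init__(self, stay_id, sensitivity, n_events):
        self.stay_id = stay_id
        self.sensitivity = sensitivity
        self.n_true_events = n_events


class TestSubgroupTest:
    def test_identical_groups_give_t0_p1(self):
        stays = [_M(f"l{i}", 0.2, 5) for i in range(3)] + [
            _M(f"h{i}", 0.9, 5) for i in range(3)
        ]
        rep = sensitivity_subgroup_test(stays)
        assert rep["computable"]
        assert rep["t_statistic"] == 0.0
        assert rep["p_value"] == 1.0

    def test_matches_frozen_welch_oracle(self):
        low = [_M(f"l{i}", 0.1, c) for i, c in enumerate([0, 0, 1])]
        high = [_M(f"h{i}", 0.9, c) for i, c in enumerate([50, 60, 70])]
        rep = sensitivity_subgroup_test(low + high)
        assert rep["t_statistic"] == pytest.approx(WELCH_T_SMALL, rel=1e-10)
        assert rep["p_value"] < 0.01
        assert rep["median_low"] == 0.0 and rep["median_high"] == 60.0

    def test_welch_statistic_matches_textbook_formula_on_random_data(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 3, 8)
        b = rng.normal(14, 5, 11)
        stays = [_M(f"l{i}", 0.1, v) for i, v in enumerate(a)] + [
            _M(f"h{i}", 0.9, v) for i, v in enumerate(b)
        ]
        rep = sensitivity_subgroup_test(stays)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert rep["t_statistic"] == pytest.approx((a.mean() - b.mean()) / se)

    def test_undefined_sensitivities_are_excluded(self):
        stays = [_M("u", None, 99)] + [_M(f"l{i}", 0.1, 1) for i in range(2)] + [
            _M(f"h{i}", 0.9, 9) for i in range(2)
        ]
        rep = sensitivity_subgroup_test(stays)
        assert rep["n_low"] == 2 and rep["n_high"] == 2

    def test_singleton_subgroup_not_computable(self):
        stays = [_M("l0", 0.1, 3)] + [_M(f"h{i}", 0.9, 5) for i in range(3)]
        rep = sensitivity_subgroup_test(stays)
        assert rep["computable"] is False
        assert rep["t_statistic"] is None


class TestChiSquare:
    def test_proportional_table_gives_zero_statistic(self):
        rep = ventilation_chisq([[20, 80], [40, 160]])
        assert rep["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rep["p_value"] == pytest.approx(1.0)

    def test_matches_hand_computed_pearson_statistic(self):
        rep = ventilation_chisq([[10, 90], [50, 50]])
        assert rep["statistic"] == pytest.approx(CHI2_TABLE, rel=1e-12)
        assert rep["df"] == 1

    def test_invariant_to_swapping_rows_and_columns(self):
        a = ventilation_chisq([[10, 90], [50, 50]])
        b = ventilation_chisq([[50, 50], [10, 90]])
        c = ventilation_chisq([[90, 10], [50, 50]])
        assert a["statistic"] == pytest.approx(b["statistic"])
        assert a["statistic"] == pytest.approx(c["statistic"])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            ventilation_chisq([[0, 0], [5, 5]])

    def test_separated_synthetic_subpopulations_are_dependent(self):
        """Cohorts with event rates 0.2 vs 2.0 per hour differ significantly
        in pooled hypoxemic-timepoint counts."""
        from spo2cast import (
            SyntheticCohortConfig,
            classify_hypoxemia,
            generate_cohort,
            prepare_series,
        )

        cfg = SyntheticCohortConfig(
            seed=21,
            subpopulations=(
                {"label": "ventilated", "n_stays": 6, "event_rate_per_hour": 2.0},
                {"label": "non-ventilated", "n_stays": 6, "event_rate_per_hour": 0.2},
            ),
        )
        table = {lbl: [0, 0] for lbl in ("ventilated", "non-ventilated")}
        for stay in generate_cohort(cfg):
            labels = classify_hypoxemia(prepare_series(stay).p_values)
            table[stay.cohort_label][0] += int(labels.sum())
            table[stay.cohort_label][1] += int((~labels).sum())
        rep = ventilation_chisq([table["ventilated"], table["non-ventilated"]])
        assert rep["p_value"] < 1e-4
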