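"""Dichotomization, ROC analysis, t-tests and correlation reports."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cogscore import (
    ASSESSMENTS,
    OptimizationConfig,
    auc,
    binarize_physician,
    composite_scores,
    correlation_report,
    dichotomize_slums,
    optimize_weights,
    rank_auc,
    roc_points,
    ttest_from_summary,
    two_sample_ttest,
    youden_operating_point,
)
from cogscore.errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidInputError,
)


class TestDichotomization:
    @pytest.mark.parametrize(
        "score, expected",
        [(20, "dementia"), (21, "control"), (0, "dementia"), (30, "control")],
    )
    def test_slums_cutoff(self, score, expected):
        assert dichotomize_slums(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            dichotomize_slums(31)

    @pytest.mark.parametrize(
        "label, expected",
        [
            ("severely_impaired", "impaired"),
            ("moderately_impaired", "impaired"),
            ("healthy", "healthy"),
        ],
    )
    def test_physician_binarization(self, label, expected):
        assert binarize_physician(label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidInputError):
            binarize_physician("mildly_confused")


def _brute_force_points(scores, labels):
    """Independent ROC oracle: count over every midpoint threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    distinct = sorted(set(scores))
    thresholds = (
        [distinct[0] - 1]
        + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
        + [distinct[-1] + 1]
    )
    pts = []
    n_pos = (labels == "impaired").sum()
    n_neg = (labels == "healthy").sum()
    for t in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if l == "impaired" and s < t)
        tn = sum(1 for s, l in zip(scores, labels) if l == "healthy" and s >= t)
        pts.append((t, tp / n_pos, tn / n_neg))
    return pts


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_points([1, 2, 9, 10], ["impaired", "impaired", "healthy", "healthy"])
        assert any(s == 1.0 and sp == 1.0 for _, s, sp in curve.points)
        assert auc(curve) == pytest.approx(1.0)
        thr, sens, spec = youden_operating_point(curve)
        assert (sens, spec) == (1.0, 1.0)

    def test_endpoints(self):
        curve = roc_points([3, 1, 2, 5], ["impaired", "healthy", "impaired", "healthy"])
        assert curve.points[0][1:] == (0.0, 1.0)
        assert curve.points[-1][1:] == (1.0, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        scores = np.round(rng.normal(15, 5, n), 1)  # rounded -> ties occur
        labels = np.where(rng.random(n) < 0.4, "impaired", "healthy")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "impaired", "healthy"
        curve = roc_points(scores, labels)
        assert [tuple(p) for p in curve.points] == pytest.approx(
            _brute_force_points(scores, labels)
        )
        # trapezoid AUC == rank statistic == sklearn (higher score = healthy)
        a = auc(curve)
        assert a == pytest.approx(rank_auc(scores, labels), abs=1e-12)
        y = (labels == "impaired").astype(int)
        assert a == pytest.approx(roc_auc_score(y, -scores), abs=1e-12)

    def test_rank_statistic_toy(self):
        scores = [1, 2, 9, 10]
        labels = ["impaired", "healthy", "impaired", "healthy"]
        assert rank_auc(scores, labels) == pytest.approx(0.75)
        assert auc(roc_points(scores, labels)) == pytest.approx(0.75)

    def test_all_ties_auc_half(self):
        curve = roc_points([5, 5, 5, 5], ["impaired", "healthy", "impaired", "healthy"])
        assert auc(curve) == pytest.approx(0.5)

    def test_null_labels_auc_near_half(self):
        rng = np.random.default_rng(12345)
        scores = rng.normal(0, 1, 2000)
        labels = np.where(rng.random(2000) < 0.5, "impaired", "healthy")
        assert auc(roc_points(scores, labels)) == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(15, 4, 30)
        labels = np.where(rng.random(30) < 0.5, "impaired", "healthy")
        a = roc_points(scores, labels)
        b = roc_points(np.exp(scores / 10), labels)
        assert a.sensitivities == pytest.approx(b.sensitivities)
        assert a.specificities == pytest.approx(b.specificities)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_points([1, 2, 3], ["healthy", "healthy", "healthy"])

    def test_youden_matches_exhaustive_search(self):
        scores = [10.0, 12.0, 14.0, 16.0, 18.0, 20.0]
        labels = ["impaired", "impaired", "healthy", "impaired", "healthy", "healthy"]
        curve = roc_points(scores, labels)
        best_j = max(s + sp - 1 for _, s, sp in curve.points)
        thr, sens, spec = youden_operating_point(curve)
        assert sens + spec - 1 == pytest.approx(best_j)
        assert (thr, sens, spec) in curve.points


class TestTTests:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_ttest(g, g)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        res = two_sample_ttest(a, a + 10)
        assert res.p_value < 1e-10
        assert res.t_statistic < 0  # first group mean is lower

    def test_raw_matches_summary(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.5, 9)
        raw = two_sample_ttest(a, b)
        summ = ttest_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert raw.t_statistic == pytest.approx(summ.t_statistic, abs=1e-10)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)

    def test_summary_matches_constructed_groups(self):
        # groups constructed to have exactly the requested mean and SD
        def construct(mean, sd, n):
            base = np.arange(n, dtype=float)
            base = (base - base.mean()) / base.std(ddof=1)
            return mean + sd * base

        a, b = construct(14.4, 3.8, 9), construct(20.4, 2.2, 9)
        raw = two_sample_ttest(a, b)
        summ = ttest_from_summary(14.4, 3.8, 9, 20.4, 2.2, 9)
        assert raw.t_statistic == pytest.approx(summ.t_statistic, abs=1e-10)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_sample_ttest([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            ttest_from_summary(1, 0.0, 5, 2, 1.0, 5)

    def test_welch_flag(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 5, 40)
        pooled = two_sample_ttest(a, b, equal_var=True)
        welch = two_sample_ttest(a, b, equal_var=False)
        assert pooled.p_value != pytest.approx(welch.p_value)


class TestCorrelationReport:
    def test_composite_identical_reference_gives_unit_r(self, equal_model, make_subject):
        rng = np.random.default_rng(6)
        cohort = []
        for i in range(20):
            adjusted = {a: float(rng.uniform(0, 1)) for a in ASSESSMENTS}
            cohort.append(make_subject(f"C{i}", adjusted))
        comp = composite_scores(cohort, equal_model)
        for s, c in zip(cohort, comp):
            s.slums = int(np.clip(round(c), 0, 30))
        # make reference exactly the (rounded) composite
        report = correlation_report(cohort, equal_model, "slums")
        assert report["composite"] >= 0.99

    def test_composite_beats_each_assessment_on_training_cohort(self, specs, random_cohort):
        res = optimize_weights(random_cohort, OptimizationConfig(seed=5, n_restarts=4), specs)
        report = correlation_report(random_cohort, res.model, "slums")
        assert report["composite"] >= max(report["per_assessment"].values()) - 1e-6

    def test_too_few_reference_scores_rejected(self, equal_model, make_subject):
        cohort = [make_subject("x", {a: 0.5 for a in ASSESSMENTS})]
        with pytest.raises(InsufficientDataError):
            correlation_report(cohort, equal_model, "mmse")
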