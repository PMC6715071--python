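"""Diagnostic validation of a fitted composite model.

Covers the standard screening-validation toolkit: dichotomization of the
reference screener (SLUMS <= 20 -> dementia) and of three-level physician
labels, ROC curves oriented so that *low* composite scores call impairment,
trapezoidal AUC with a rank-statistic cross-check, a Youden-J operating
point, pooled two-sample t-tests (from raw data or from printed summary
statistics alone), and direction-adjusted correlation reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

from .battery import (
    CompositeModel,
    SubjectRecord,
    adjusted_matrix,
    composite_from_adjusted,
    DEFAULT_MIN_ASSESSMENTS,
)
from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidInputError,
)
from .optimize import pearson_correlation

#: SLUMS cutoff: scores at or below this value are classified as dementia.
SLUMS_DEMENTIA_CUTOFF = 20


@dataclass(frozen=True)
class RocCurve:
    """Operating points (threshold, sensitivity, specificity), positive below threshold."""

    points: tuple[tuple[float, float, float], ...]
    positive_label: str = "impaired"
    orientation: str = "positive_if_score_below_threshold"

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def specificities(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary plus the pooled (or Welch) two-sided t-test."""

    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    t_statistic: float
    p_value: float


def dichotomize_slums(score: int) -> str:
    """SLUMS 0-30 -> 'dementia' (<= 20) or 'control' (>= 21)."""
    if not 0 <= score <= 30:
        raise InvalidInputError(f"SLUMS score {score} outside [0, 30]")
    return "dementia" if score <= SLUMS_DEMENTIA_CUTOFF else "control"


def binarize_physician(label: str) -> str:
    """Collapse moderate + severe impairment into one 'impaired' class."""
    if label == "healthy":
        return "healthy"
    if label in ("moderately_impaired", "severely_impaired"):
        return "impaired"
    raise InvalidInputError(f"unknown physician label {label!r}")


def roc_points(scores: Sequence[float], labels: Sequence[str]) -> RocCurve:
    """ROC curve for an impairment score where lower values flag impairment.

    Thresholds sit at midpoints between consecutive distinct scores, plus a
    sentinel below the minimum (nothing positive) and above the maximum
    (everything positive); a subject is called positive when score < threshold,
    so ties can never straddle a threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size or scores.size < 2:
        raise InvalidInputError("need >= 2 paired scores and labels")
    impaired = labels == "impaired"
    healthy = labels == "healthy"
    if not (impaired | healthy).all():
        bad = set(labels) - {"impaired", "healthy"}
        raise InvalidInputError(f"unknown labels {bad}")
    n_pos, n_neg = int(impaired.sum()), int(healthy.sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both impaired and healthy subjects are required")

    distinct = np.unique(scores)
    thresholds = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    pts = []
    for t in thresholds:
        positive = scores < t
        sens = float((positive & impaired).sum() / n_pos)
        spec = float((~positive & healthy).sum() / n_neg)
        pts.append((float(t), sens, spec))
    return RocCurve(points=tuple(pts))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve in (1 - specificity, sensitivity)."""
    fpr = 1.0 - curve.specificities
    tpr = curve.sensitivities
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def rank_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC as the rank statistic P(impaired < healthy) + 0.5 P(tie).

    Mathematically identical to the trapezoidal area; kept separate as an
    internal cross-check of the curve construction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    imp = scores[labels == "impaired"]
    hea = scores[labels == "healthy"]
    if imp.size == 0 or hea.size == 0:
        raise DegenerateLabelsError("both classes required")
    less = (imp[:, None] < hea[None, :]).sum()
    ties = (imp[:, None] == hea[None, :]).sum()
    return float((less + 0.5 * ties) / (imp.size * hea.size))


def youden_operating_point(curve: RocCurve) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties go to the point with higher specificity, then lower threshold.
    """
    best = None
    for thr, sens, spec in curve.points:
        j = sens + spec - 1.0
        key = (j, spec, -thr)
        if best is None or key > best[0]:
            best = (key, (thr, sens, spec))
    return best[1]


def two_sample_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided two-sample t-test, pooled variance by default (Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    res = _sstats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        group_ns=(int(a.size), int(b.size)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def ttest_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = True,
) -> GroupComparison:
    """Pooled two-sided t-test computed from summary statistics alone.

    Useful when only printed group means/SDs/ns are available, e.g. checking
    a reported significance bound without per-subject data.
    """
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise InvalidInputError("group SDs must be positive")
    res = _sstats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return GroupComparison(
        group_means=(mean_a, mean_b),
        group_sds=(sd_a, sd_b),
        group_ns=(int(n_a), int(n_b)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def composite_scores(
    cohort: Sequence[SubjectRecord],
    model: CompositeModel,
    min_assessments: int = DEFAULT_MIN_ASSESSMENTS,
) -> np.ndarray:
    """Composite for every subject; NaN where the battery is too incomplete."""
    adjusted, names = adjusted_matrix(cohort, model.specs)
    w = np.array([model.weights.get(n, 0.0) for n in names])
    return composite_from_adjusted(adjusted, w, model.total, min_assessments)


def correlation_report(
    cohort: Sequence[SubjectRecord],
    model: CompositeModel,
    reference: str,
) -> dict:
    """Direction-adjusted per-assessment r plus composite r against a reference.

    All correlations are pairwise-complete; direction adjustment makes the
    expected sign positive for every assessment.
    """
    ref = np.array(
        [np.nan if s.reference(reference) is None else float(s.reference(reference)) for s in cohort]
    )
    if np.sum(~np.isnan(ref)) < 3:
        raise InsufficientDataError(f"fewer than 3 subjects carry {reference} scores")
    adjusted, names = adjusted_matrix(cohort, model.specs)
    per_assessment: dict[str, float] = {}
    for j, name in enumerate(names):
        try:
            per_assessment[name] = pearson_correlation(adjusted[:, j], ref)
        except Exception:
            per_assessment[name] = float("nan")
    comp = composite_scores(cohort, model)
    return {
        "reference": reference,
        "per_assessment": per_assessment,
        "composite": pearson_correlation(comp, ref),
    }


def validate_model(
    cohort: Sequence[SubjectRecord],
    model: CompositeModel,
    reference: str = "slums",
) -> dict:
    """Full validation report: correlations, group test, ROC, AUC, Youden point.

    Binary labels come from the reference dichotomization (SLUMS cutoff) or,
    if physician labels are present for all subjects, from those instead.
    """
    report = correlation_report(cohort, model, reference)
    comp = composite_scores(cohort, model)

    labels = []
    for s in cohort:
        if s.physician_label is not None:
            labels.append(binarize_physician(s.physician_label))
        elif reference == "slums" and s.slums is not None:
            labels.append(
                "impaired" if dichotomize_slums(s.slums) == "dementia" else "healthy"
            )
        else:
            labels.append(None)
    keep = [i for i, (l, c) in enumerate(zip(labels, comp)) if l and not np.isnan(c)]
    scores = comp[keep]
    labs = [labels[i] for i in keep]

    out = {"correlations": report, "n_scored": int(np.sum(~np.isnan(comp)))}
    if len(set(labs)) == 2:
        curve = roc_points(scores, labs)
        thr, sens, spec = youden_operating_point(curve)
        imp = scores[np.array(labs) == "impaired"]
        hea = scores[np.array(labs) == "healthy"]
        ttest = two_sample_ttest(imp, hea)
        out.update(
            {
                "roc": [list(p) for p in curve.points],
                "auc": auc(curve),
                "operating_point": {
                    "threshold": thr,
                    "sensitivity": sens,
                    "specificity": spec,
                },
                "group_comparison": {
                    "impaired_mean": ttest.group_means[0],
                    "healthy_mean": ttest.group_means[1],
                    "impaired_sd": ttest.group_sds[0],
                    "healthy_sd": ttest.group_sds[1],
                    "ns": list(ttest.group_ns),
                    "t": ttest.t_statistic,
                    "p": ttest.p_value,
                },
            }
        )
    return out
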