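"""Correlation-maximizing weight fitting for the composite score.

The fitting problem: choose nonnegative weights summing to a fixed total so
that the composite score correlates maximally (Pearson) with a reference
screener (SLUMS, MMSE or MoCA) over a training cohort.  Because Pearson
correlation is invariant to positive rescaling of the composite, the search
runs on the unit simplex and the winner is rescaled to the 30-point total
afterwards — exactly, not approximately.

The search itself is a derivative-free Nelder-Mead descent on a softmax
reparameterization of the simplex (unconstrained R^k -> simplex interior),
run from an equal-weight start, from each simplex vertex, and from
``n_restarts`` seeded random starts; the best restart wins, ties going to
the earlier start.  The exact vertices are also evaluated directly, so the
achieved correlation can never fall below the best single assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as _sopt
from scipy import stats as _sstats

from .battery import (
    ASSESSMENTS,
    DEFAULT_MIN_ASSESSMENTS,
    DEFAULT_TOTAL,
    AssessmentSpec,
    CompositeModel,
    SubjectRecord,
    adjusted_matrix,
    normalize_weights,
)
from .errors import InsufficientDataError, UndefinedCorrelationError


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the weight fit; defaults reproduce the standard pipeline."""

    reference: str = "slums"
    n_restarts: int = 16
    seed: int = 0
    tolerance: float = 1e-8
    total: float = DEFAULT_TOTAL
    min_assessments: int = DEFAULT_MIN_ASSESSMENTS
    max_evaluations: int = 10_000

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FitResult:
    """Fitted model plus the diagnostics a report needs."""

    model: CompositeModel
    achieved_correlation: float
    per_assessment_correlations: dict[str, float]
    n_subjects_used: int
    config: OptimizationConfig | None = field(default=None, repr=False)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with pairwise-complete missing handling.

    Pairs where either member is NaN are dropped; fewer than three complete
    pairs or a constant margin raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedCorrelationError(f"only {x.size} complete pairs, need >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(_sstats.pearsonr(x, y).statistic)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _prepare_design(
    cohort: Sequence[SubjectRecord],
    specs: Mapping[str, AssessmentSpec],
    reference: str,
    min_assessments: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Adjusted-score matrix and reference vector over usable subjects.

    Usable = reference score present and at least ``min_assessments`` metrics
    present.  Direction adjustment makes every column point the same way
    (higher = better), so any nonnegative weighting preserves orientation.
    """
    with_ref = [s for s in cohort if s.reference(reference) is not None]
    adjusted, names = adjusted_matrix(with_ref, specs)
    enough = (~np.isnan(adjusted)).sum(axis=1) >= min_assessments
    adjusted = adjusted[enough]
    ref = np.array(
        [float(s.reference(reference)) for s, ok in zip(with_ref, enough) if ok]
    )
    return adjusted, ref, names


def _objective_factory(adjusted: np.ndarray, ref: np.ndarray):
    """Return r(weights) over the usable cohort; NaN-safe, renormalized."""
    mask = ~np.isnan(adjusted)
    filled = np.nan_to_num(adjusted)

    def corr_of(weights: np.ndarray) -> float:
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = (filled @ weights) / (mask @ weights)
        keep = ~np.isnan(comp)
        c, r = comp[keep], ref[keep]
        if c.size < 3 or np.ptp(c) == 0:
            return -np.inf
        c = c - c.mean()
        r = r - r.mean()
        denom = np.sqrt((c @ c) * (r @ r))
        return float((c @ r) / denom) if denom > 0 else -np.inf

    return corr_of


def optimize_weights(
    cohort: Sequence[SubjectRecord],
    config: OptimizationConfig,
    specs: Mapping[str, AssessmentSpec],
) -> FitResult:
    """Fit composite weights maximizing Pearson r against the reference.

    Deterministic given ``config.seed``; raises
    :class:`InsufficientDataError` below 10 usable subjects and
    :class:`UndefinedCorrelationError` for a constant reference.
    """
    adjusted, ref, names = _prepare_design(
        cohort, specs, config.reference, config.min_assessments
    )
    n_used = ref.size
    if n_used < 10:
        raise InsufficientDataError(
            f"{n_used} usable subjects with {config.reference} scores, need >= 10"
        )
    if np.ptp(ref) == 0:
        raise UndefinedCorrelationError("reference scores are constant")

    corr_of = _objective_factory(adjusted, ref)
    k = len(names)
    rng = np.random.default_rng(config.seed)

    # starts: equal weights, every simplex vertex, then seeded random draws
    starts = [np.zeros(k)]
    starts += [8.0 * np.eye(k)[j] for j in range(k)]
    starts += [rng.normal(size=k) for _ in range(config.n_restarts)]

    best_r, best_w = -np.inf, np.full(k, 1.0 / k)
    # exact vertices first, so the single-best-assessment bound always holds
    for j in range(k):
        r = corr_of(np.eye(k)[j])
        if r > best_r:
            best_r, best_w = r, np.eye(k)[j]

    for z0 in starts:
        res = _sopt.minimize(
            lambda z: -corr_of(_softmax(z)),
            z0,
            method="Nelder-Mead",
            options={
                "maxfev": config.max_evaluations,
                "fatol": config.tolerance,
                "xatol": 1e-6,
            },
        )
        w = _softmax(res.x)
        r = corr_of(w)
        if r > best_r:
            best_r, best_w = r, w

    weights = normalize_weights(dict(zip(names, best_w)), total=config.total)
    # zero-weight any assessment absent from weights map? names covers specs.
    model = CompositeModel(weights=weights, specs=dict(specs), total=config.total)

    per_assessment: dict[str, float] = {}
    for j, name in enumerate(names):
        col = adjusted[:, j]
        try:
            per_assessment[name] = pearson_correlation(col, ref)
        except UndefinedCorrelationError:
            per_assessment[name] = float("nan")

    return FitResult(
        model=model,
        achieved_correlation=best_r,
        per_assessment_correlations=per_assessment,
        n_subjects_used=int(n_used),
        config=config,
    )


def _simplex_grid(k: int, steps: int):
    """Yield all length-k nonnegative integer compositions of ``steps``."""
    if k == 1:
        yield (steps,)
        return
    for first in range(steps + 1):
        for rest in _simplex_grid(k - 1, steps - first):
            yield (first,) + rest


def grid_oracle(
    cohort: Sequence[SubjectRecord],
    specs: Mapping[str, AssessmentSpec],
    resolution: float,
    reference: str = "slums",
    total: float = DEFAULT_TOTAL,
    min_assessments: int = DEFAULT_MIN_ASSESSMENTS,
) -> tuple[dict[str, float], float]:
    """Exhaustive simplex-grid search; the slow, obviously-correct fitter.

    Enumerates every weight vector whose entries are multiples of
    ``resolution`` summing to 1, and returns the best (weights scaled to
    ``total``, achieved r).  Intended as a test oracle at coarse resolution.
    """
    adjusted, ref, names = _prepare_design(cohort, specs, reference, min_assessments)
    if ref.size < 3:
        raise InsufficientDataError("too few usable subjects for the grid oracle")
    if np.ptp(ref) == 0:
        raise UndefinedCorrelationError("reference scores are constant")
    corr_of = _objective_factory(adjusted, ref)
    steps = round(1.0 / resolution)
    best_r, best_w = -np.inf, None
    for comp in _simplex_grid(len(names), steps):
        w = np.asarray(comp, dtype=float) / steps
        r = corr_of(w)
        if r > best_r:
            best_r, best_w = r, w
    weights = {n: float(w * total) for n, w in zip(names, best_w)}
    return weights, best_r
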