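"""Battery definition, score scaling and the 0-30 weighted composite.

The battery consists of seven assessments summarised by one raw metric each:
two recall fractions, a matrix-problem fraction, three reaction times and a
digit-symbol rate.  Each raw metric is min-max scaled into [0, 1]; reaction
times point the "wrong" way (higher = worse), so their contribution to the
composite uses ``1 - s`` instead of ``s``.  Weights are nonnegative and sum
to a fixed total (30 by convention, mirroring common paper-and-pencil
screeners), which bounds the composite to [0, 30] with lower values
indicating greater impairment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import IncompleteBatteryError, InvalidInputError, InvalidWeightsError

#: Canonical assessment order used throughout the package.
ASSESSMENTS: tuple[str, ...] = (
    "immediate_recall",
    "delayed_recall",
    "stroop_rt",
    "trails_a_rt",
    "trails_b_rt",
    "matrix",
    "digit_symbol",
)

METRIC_KINDS = ("fraction_correct", "reaction_time_seconds", "rate_per_second")
DIRECTIONS = ("higher_is_better", "lower_is_better")

#: Normative mean and SD of each raw metric (fractions in [0,1], times in
#: seconds, digit-symbol in correct responses per second).
NORMATIVE_STATS: dict[str, tuple[float, float]] = {
    "immediate_recall": (0.94, 0.07),
    "delayed_recall": (0.91, 0.09),
    "stroop_rt": (2.28, 0.74),
    "trails_a_rt": (1.05, 0.44),
    "trails_b_rt": (1.96, 0.98),
    "matrix": (0.83, 0.18),
    "digit_symbol": (0.44, 0.14),
}

_METRIC_KIND: dict[str, str] = {
    "immediate_recall": "fraction_correct",
    "delayed_recall": "fraction_correct",
    "stroop_rt": "reaction_time_seconds",
    "trails_a_rt": "reaction_time_seconds",
    "trails_b_rt": "reaction_time_seconds",
    "matrix": "fraction_correct",
    "digit_symbol": "rate_per_second",
}

DEFAULT_TOTAL = 30.0
DEFAULT_MIN_ASSESSMENTS = 4


@dataclass(frozen=True)
class AssessmentSpec:
    """Identity, direction and scaling bounds of one battery metric.

    ``scale_min``/``scale_max`` are in raw-metric units; ``scale_score``
    maps the raw value linearly onto [0, 1] between them, clamping outside.
    """

    name: str
    metric_kind: str
    direction: str
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise InvalidInputError(f"unknown metric_kind {self.metric_kind!r}")
        if self.direction not in DIRECTIONS:
            raise InvalidInputError(f"unknown direction {self.direction!r}")
        if not (self.scale_min < self.scale_max):
            raise InvalidInputError(
                f"{self.name}: scale_min must be < scale_max "
                f"({self.scale_min} >= {self.scale_max})"
            )
        if self.metric_kind == "fraction_correct":
            if (self.scale_min, self.scale_max) != (0.0, 1.0):
                raise InvalidInputError(
                    f"{self.name}: fraction_correct metrics scale on [0, 1]"
                )
            if self.direction != "higher_is_better":
                raise InvalidInputError(
                    f"{self.name}: fraction_correct metrics are higher_is_better"
                )
        if self.metric_kind == "reaction_time_seconds" and self.direction != "lower_is_better":
            raise InvalidInputError(f"{self.name}: reaction times are lower_is_better")


def default_specs() -> dict[str, AssessmentSpec]:
    """Default specs for the seven-assessment battery.

    Fraction metrics scale on their natural [0, 1] range.  Reaction times and
    the digit-symbol rate scale between the normative mean -/+ 3 SD (floored
    at 0), so a typical performance sits mid-scale and extreme values clamp.
    """
    specs: dict[str, AssessmentSpec] = {}
    for name in ASSESSMENTS:
        kind = _METRIC_KIND[name]
        if kind == "fraction_correct":
            lo, hi, direction = 0.0, 1.0, "higher_is_better"
        else:
            mean, sd = NORMATIVE_STATS[name]
            lo = max(0.0, mean - 3.0 * sd)
            hi = mean + 3.0 * sd
            direction = "lower_is_better" if kind == "reaction_time_seconds" else "higher_is_better"
        specs[name] = AssessmentSpec(name, kind, direction, lo, hi)
    return specs


@dataclass
class SubjectRecord:
    """One participant: raw metrics, optional reference scores and labels."""

    subject_id: str
    raw_metrics: dict[str, float] = field(default_factory=dict)
    age: float | None = None
    sex: str | None = None
    slums: int | None = None
    mmse: int | None = None
    moca: int | None = None
    physician_label: str | None = None

    def __post_init__(self) -> None:
        for name, value in self.raw_metrics.items():
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"subject {self.subject_id}: metric {name}={value} "
                    "must be finite and nonnegative"
                )
        for ref in ("slums", "mmse", "moca"):
            score = getattr(self, ref)
            if score is not None and not (0 <= score <= 30):
                raise InvalidInputError(
                    f"subject {self.subject_id}: {ref}={score} outside [0, 30]"
                )

    def reference(self, which: str) -> int | None:
        if which not in ("slums", "mmse", "moca"):
            raise InvalidInputError(f"unknown reference instrument {which!r}")
        return getattr(self, which)


@dataclass(frozen=True)
class ScaledScores:
    """Per-assessment scaled scores in [0, 1] plus the completeness set."""

    values: Mapping[str, float]
    completeness: frozenset[str]


@dataclass(frozen=True)
class CompositeResult:
    """A composite value together with the assessments that produced it."""

    value: float
    completeness: frozenset[str]


@dataclass
class CompositeModel:
    """Normalized weights plus the scaling specs they apply to."""

    weights: dict[str, float]
    specs: dict[str, AssessmentSpec]
    total: float = DEFAULT_TOTAL

    def __post_init__(self) -> None:
        if not self.weights:
            raise InvalidWeightsError("model has no weights")
        for name, w in self.weights.items():
            if w < 0:
                raise InvalidWeightsError(f"negative weight for {name}: {w}")
            if name not in self.specs:
                raise InvalidWeightsError(f"weighted assessment {name} has no spec")
        s = sum(self.weights.values())
        if abs(s - self.total) > 1e-9 * max(1.0, self.total):
            raise InvalidWeightsError(
                f"weights sum to {s}, expected total {self.total}"
            )


def scale_score(raw: float, spec: AssessmentSpec) -> float:
    """Min-max scale a raw metric onto [0, 1], clamping outside the bounds."""
    if not math.isfinite(raw):
        raise InvalidInputError(f"raw value for {spec.name} is not finite: {raw}")
    s = (raw - spec.scale_min) / (spec.scale_max - spec.scale_min)
    return min(1.0, max(0.0, s))


def contribution(s_a: float, w_a: float, direction: str) -> float:
    """Direction-aware weighted contribution: w*s or w*(1-s) for reaction times."""
    if not 0.0 <= s_a <= 1.0:
        raise InvalidInputError(f"scaled score {s_a} outside [0, 1]")
    if w_a < 0:
        raise InvalidInputError(f"weight must be nonnegative, got {w_a}")
    if direction not in DIRECTIONS:
        raise InvalidInputError(f"unknown direction {direction!r}")
    return w_a * s_a if direction == "higher_is_better" else w_a * (1.0 - s_a)


def normalize_weights(raw_weights: Mapping[str, float], total: float = DEFAULT_TOTAL) -> dict[str, float]:
    """Rescale nonnegative weights so they sum exactly to ``total``."""
    if total <= 0:
        raise InvalidWeightsError(f"total must be positive, got {total}")
    if any(w < 0 for w in raw_weights.values()):
        raise InvalidWeightsError("weights must be nonnegative")
    s = sum(raw_weights.values())
    if s <= 0:
        raise InvalidWeightsError("at least one weight must be strictly positive")
    return {name: w * total / s for name, w in raw_weights.items()}


def scaled_scores(subject: SubjectRecord, specs: Mapping[str, AssessmentSpec]) -> ScaledScores:
    """Scale every present raw metric of a subject."""
    values = {
        name: scale_score(raw, specs[name])
        for name, raw in subject.raw_metrics.items()
        if name in specs
    }
    return ScaledScores(values=values, completeness=frozenset(values))


def composite_score(
    subject: SubjectRecord,
    model: CompositeModel,
    min_assessments: int = DEFAULT_MIN_ASSESSMENTS,
) -> CompositeResult:
    """Composite score of one subject on the model's [0, total] scale.

    Subjects with an incomplete battery are scored by renormalizing the
    weights of the *present* assessments to the same total, which keeps every
    composite on one scale; fewer than ``min_assessments`` present raises
    :class:`IncompleteBatteryError`.
    """
    ss = scaled_scores(subject, model.specs)
    present = [name for name in model.weights if name in ss.values]
    if len(present) < min_assessments:
        raise IncompleteBatteryError(
            f"subject {subject.subject_id}: {len(present)} assessments present, "
            f"minimum is {min_assessments}"
        )
    weight_mass = sum(model.weights[name] for name in present)
    if weight_mass <= 0:
        raise InvalidWeightsError(
            f"subject {subject.subject_id}: present assessments carry zero weight"
        )
    scale = model.total / weight_mass
    value = sum(
        contribution(ss.values[name], model.weights[name] * scale, model.specs[name].direction)
        for name in present
    )
    # guard against float drift at the extremes
    value = min(model.total, max(0.0, value))
    return CompositeResult(value=value, completeness=frozenset(present))


def adjusted_matrix(
    records: Sequence[SubjectRecord],
    specs: Mapping[str, AssessmentSpec],
    names: Iterable[str] = ASSESSMENTS,
) -> tuple[np.ndarray, list[str]]:
    """Direction-adjusted scaled scores as an (n_subjects, n_assessments) array.

    Entry [i, a] is s_ia for higher_is_better metrics and 1 - s_ia for
    lower_is_better ones, so larger always means better cognition; absent
    metrics are NaN.  This is the vectorized kernel behind batch composite
    scoring and the weight optimizer.
    """
    names = [n for n in names if n in specs]
    out = np.full((len(records), len(names)), np.nan)
    for i, rec in enumerate(records):
        for j, name in enumerate(names):
            raw = rec.raw_metrics.get(name)
            if raw is None:
                continue
            s = scale_score(raw, specs[name])
            out[i, j] = s if specs[name].direction == "higher_is_better" else 1.0 - s
    return out, names


def composite_from_adjusted(
    adjusted: np.ndarray,
    weights: np.ndarray,
    total: float = DEFAULT_TOTAL,
    min_assessments: int = DEFAULT_MIN_ASSESSMENTS,
) -> np.ndarray:
    """Batch composite from an adjusted-score matrix; NaN where too incomplete.

    Equivalent to :func:`composite_score` row by row (weights renormalized
    over the present subset), but vectorized for the optimizer's inner loop.
    """
    mask = ~np.isnan(adjusted)
    present_mass = mask @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.nansum(adjusted * weights, axis=1)
        comp = total * raw / present_mass
    comp[(mask.sum(axis=1) < min_assessments) | (present_mass <= 0)] = np.nan
    return np.clip(comp, 0.0, total)
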