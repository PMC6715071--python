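import numpy as np
import pytest

from cogscore import (
    ASSESSMENTS,
    AssessmentSpec,
    CompositeModel,
    SubjectRecord,
    default_specs,
    normalize_weights,
)


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def equal_model(specs):
    weights = normalize_weights({name: 1.0 for name in ASSESSMENTS})
    return CompositeModel(weights=weights, specs=specs)


def raw_from_adjusted(adjusted: dict[str, float], specs) -> dict[str, float]:
    """Invert scaling + direction so a subject's adjusted scores are exact.

    ``adjusted`` maps assessment -> desired direction-adjusted scaled score
    (1 = best performance); returns the raw metric values producing it.
    """
    raw = {}
    for name, d in adjusted.items():
        spec = specs[name]
        s = d if spec.direction == "higher_is_better" else 1.0 - d
        raw[name] = spec.scale_min + s * (spec.scale_max - spec.scale_min)
    return raw


@pytest.fixture(scope="session")
def make_subject(specs):
    def _make(subject_id: str, adjusted: dict[str, float], **kwargs) -> SubjectRecord:
        return SubjectRecord(
            subject_id=subject_id,
            raw_metrics=raw_from_adjusted(adjusted, specs),
            **kwargs,
        )

    return _make


@pytest.fixture(scope="session")
def random_cohort(specs, make_subject):
    """Small cohort with SLUMS scores loosely tracking overall performance."""
    rng = np.random.default_rng(42)
    subjects = []
    for i in range(40):
        adjusted = {name: float(rng.uniform(0.05, 0.95)) for name in ASSESSMENTS}
        slums = int(np.clip(round(np.mean(list(adjusted.values())) * 25 + rng.normal(0, 2)), 0, 30))
        subjects.append(make_subject(f"R{i:03d}", adjusted, slums=slums))
    return subjects
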