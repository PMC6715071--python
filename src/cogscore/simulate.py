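"""Single-latent-factor synthetic cohort generator.

Real per-subject battery data are not publicly deposited, so every pipeline
stage is exercised on simulated cohorts with the statistical structure the
analysis assumes: one latent cognitive-status factor theta drives all seven
assessment metrics and the 0-30 reference screeners.  Each raw metric is

    raw = mu + sigma * (s * lambda_a * theta + sqrt(1 - lambda_a^2) * eps)

with s = -1 for reaction times (higher theta = better cognition = faster),
then clamped to its physical range (fractions to [0, 1], times and rates
floored at a small positive value).  Because several normative targets sit
close to a bound (immediate recall 0.94 with SD 0.07 spends ~20% of its
normal mass above 1), (mu, sigma) are NOT the targets themselves: they are
solved per metric so that the post-clamp mean and SD equal the normative
targets exactly in population.  Parameter-recovery tests then check the
sample statistics against those targets within sampling error.

Default loadings (assessments 0.76, reference 0.85) put each assessment's
expected correlation with the reference at 0.76 * 0.85 = 0.646 — the middle
of the moderate range such screeners show — and the population correlation
of the optimal equal-weight composite at 0.809 (see
:func:`expected_composite_correlation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize as _sopt
from scipy.special import ndtr

from .battery import (
    ASSESSMENTS,
    NORMATIVE_STATS,
    SubjectRecord,
    default_specs,
)
from .errors import ConfigError, InvalidInputError

#: Physical floor for generated times and rates (seconds / correct-per-second).
TIME_FLOOR = 0.01

_LOWER_IS_BETTER = {"stroop_rt", "trails_a_rt", "trails_b_rt"}
_FRACTIONS = {"immediate_recall", "delayed_recall", "matrix"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic-cohort generator.

    ``metric_means``/``metric_sds`` are the raw-metric normative targets the
    generated cohort should recover; ``lambda_assessment`` and
    ``lambda_reference`` are factor loadings of the scaled metrics and of the
    reference screener on the latent factor; ``ref_mean``/``ref_sd`` place
    the reference screener on its 0-30 scale; ``impaired_fraction`` and
    ``group_shift`` (latent-SD units) configure two-group cohorts.
    """

    n: int = 398
    seed: int = 0
    metric_means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in NORMATIVE_STATS.items()}
    )
    metric_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in NORMATIVE_STATS.items()}
    )
    lambda_assessment: float = 0.76
    lambda_reference: float = 0.85
    impaired_fraction: float = 0.0
    group_shift: float = 0.0
    missing_rate: float = 0.0
    age_mean: float = 70.2
    age_sd: float = 9.0
    ref_mean: float = 20.0
    ref_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not (0.0 < self.lambda_assessment < 1.0) or not (0.0 < self.lambda_reference < 1.0):
            raise ConfigError("factor loadings must lie in (0, 1)")
        if not (0.0 <= self.impaired_fraction <= 1.0):
            raise ConfigError("impaired_fraction must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        for name in ASSESSMENTS:
            if name not in self.metric_means or name not in self.metric_sds:
                raise ConfigError(f"missing calibration for metric {name}")
            if self.metric_sds[name] <= 0:
                raise ConfigError(f"metric SD for {name} must be positive")


@dataclass
class SyntheticCohort:
    """Generated subjects plus the latent factor values that produced them."""

    subjects: list[SubjectRecord]
    latent_theta: np.ndarray
    config_echo: GeneratorConfig


def _clamped_normal_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of clamp(N(mu, sigma), lo, hi), in closed form."""
    a = (lo - mu) / sigma
    phi_a = math.exp(-0.5 * a * a) / math.sqrt(2 * math.pi)
    Phi_a = float(ndtr(a))
    if math.isinf(hi):
        b, phi_b, Phi_b, hi_term1, hi_term2, b_phi_b = 0.0, 0.0, 1.0, 0.0, 0.0, 0.0
    else:
        b = (hi - mu) / sigma
        phi_b = math.exp(-0.5 * b * b) / math.sqrt(2 * math.pi)
        Phi_b = float(ndtr(b))
        hi_term1 = hi * (1.0 - Phi_b)
        hi_term2 = hi * hi * (1.0 - Phi_b)
        b_phi_b = b * phi_b
    z = Phi_b - Phi_a
    m1 = lo * Phi_a + hi_term1 + mu * z + sigma * (phi_a - phi_b)
    m2 = (
        lo * lo * Phi_a
        + hi_term2
        + mu * mu * z
        + 2.0 * mu * sigma * (phi_a - phi_b)
        + sigma * sigma * (z + a * phi_a - b_phi_b)
    )
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


@lru_cache(maxsize=256)
def _pre_clamp_params(target_mean: float, target_sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Normal (mu, sigma) whose clamp to [lo, hi] has the target mean and SD."""

    def residual(x):
        mu, log_sigma = x
        m, s = _clamped_normal_moments(mu, math.exp(log_sigma), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = _sopt.root(residual, x0=[target_mean, math.log(target_sd)], tol=1e-12)
    if not sol.success:
        raise ConfigError(
            f"cannot calibrate clamped normal to mean={target_mean}, sd={target_sd} "
            f"on [{lo}, {hi}]"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _metric_bounds(name: str) -> tuple[float, float]:
    return (0.0, 1.0) if name in _FRACTIONS else (TIME_FLOOR, math.inf)


def _draw_metrics(theta: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Raw metric draws given latent factor values, calibrated and clamped."""
    lam = config.lambda_assessment
    resid = math.sqrt(1.0 - lam * lam)
    out: dict[str, np.ndarray] = {}
    for name in ASSESSMENTS:
        lo, hi = _metric_bounds(name)
        mu, sigma = _pre_clamp_params(config.metric_means[name], config.metric_sds[name], lo, hi)
        sign = -1.0 if name in _LOWER_IS_BETTER else 1.0
        z = sign * lam * theta + resid * rng.standard_normal(theta.size)
        out[name] = np.clip(mu + sigma * z, lo, None if math.isinf(hi) else hi)
    return out


def _assemble(
    theta: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    reference: str | None = None,
    physician_labels: list[str] | None = None,
    id_prefix: str = "S",
) -> SyntheticCohort:
    n = theta.size
    metrics = _draw_metrics(theta, config, rng)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 50.0, None)
    sexes = np.where(rng.random(n) < 0.8, "F", "M")

    ref_scores = None
    if reference is not None:
        lam = config.lambda_reference
        z = lam * theta + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
        ref_scores = np.clip(np.rint(config.ref_mean + config.ref_sd * z), 0, 30).astype(int)

    missing = (
        rng.random((n, len(ASSESSMENTS))) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, len(ASSESSMENTS)), dtype=bool)
    )

    subjects = []
    for i in range(n):
        raw = {
            name: float(metrics[name][i])
            for j, name in enumerate(ASSESSMENTS)
            if not missing[i, j]
        }
        kwargs: dict = {}
        if reference is not None:
            kwargs[reference] = int(ref_scores[i])
        if physician_labels is not None:
            kwargs["physician_label"] = physician_labels[i]
        subjects.append(
            SubjectRecord(
                subject_id=f"{id_prefix}{i:04d}",
                raw_metrics=raw,
                age=float(ages[i]),
                sex=str(sexes[i]),
                **kwargs,
            )
        )
    return SyntheticCohort(subjects=subjects, latent_theta=theta, config_echo=config)


def _rng(config: GeneratorConfig, seed: int | None) -> tuple[np.random.Generator, GeneratorConfig]:
    if seed is not None:
        config = replace(config, seed=seed)
    return np.random.default_rng(config.seed), config


def simulate_normative(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Normative cohort: theta ~ N(0, 1), no reference scores or labels."""
    rng, config = _rng(config, seed)
    theta = rng.standard_normal(config.n)
    return _assemble(theta, config, rng, id_prefix="N")


def simulate_comparison(
    config: GeneratorConfig,
    seed: int | None = None,
    reference: str = "slums",
) -> SyntheticCohort:
    """Comparison cohort carrying an integer 0-30 reference screener score."""
    if reference not in ("slums", "mmse", "moca"):
        raise ConfigError(f"unknown reference instrument {reference!r}")
    rng, config = _rng(config, seed)
    theta = rng.standard_normal(config.n)
    return _assemble(theta, config, rng, reference=reference, id_prefix="C")


def simulate_physician_substudy(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Two-group cohort with three-level physician labels.

    Exactly round(n * impaired_fraction) subjects form the impaired
    component, whose latent factor is shifted down by ``group_shift``;
    within it the lowest-theta third is labelled severely impaired and the
    rest moderately impaired.
    """
    rng, config = _rng(config, seed)
    n_impaired = int(round(config.n * config.impaired_fraction))
    n_healthy = config.n - n_impaired
    theta_h = rng.standard_normal(n_healthy)
    theta_i = rng.standard_normal(n_impaired) - config.group_shift

    labels = ["healthy"] * n_healthy
    if n_impaired:
        n_severe = int(round(n_impaired / 3))
        order = np.argsort(theta_i)
        imp_labels = np.array(["moderately_impaired"] * n_impaired, dtype=object)
        imp_labels[order[:n_severe]] = "severely_impaired"
        labels += list(imp_labels)
    theta = np.concatenate([theta_h, theta_i])
    return _assemble(theta, config, rng, physician_labels=labels, id_prefix="P")


def expected_composite_correlation(k: int, lambda_a: float, lambda_ref: float) -> float:
    """Population r between an equal-weight composite of k equally loaded
    indicators and the reference screener, under the one-factor model:

        r = lambda_ref * sqrt(k * lambda_a^2 / (1 + (k - 1) * lambda_a^2))
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if not (0.0 < lambda_a <= 1.0) or not (0.0 < lambda_ref <= 1.0):
        raise InvalidInputError("loadings must lie in (0, 1]")
    la2 = lambda_a * lambda_a
    return lambda_ref * math.sqrt(k * la2 / (1.0 + (k - 1) * la2))


def scoring_specs():
    """Default battery specs matching the generator's calibration targets."""
    return default_specs()
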