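# Methods

## Composite score

Each of the seven battery metrics is reduced to a scaled score
s_a ∈ [0, 1] by min–max scaling against per-assessment bounds stored in its
`AssessmentSpec`, clamping outside them. Fraction-correct metrics
(immediate/delayed recall, matrix) use their natural [0, 1] range; reaction
times (Stroop, Trails A/B) and the digit-symbol rate use normative mean ∓ 3 SD
(floored at 0), so a typical performance sits mid-scale and only extreme
values clamp. The bounds are configuration, not estimated from the cohort
being scored, which keeps scoring leakage-free and comparable across cohorts.

Contributions are direction-aware — c_a = w_a·s_a when higher raw values mean
better performance, c_a = w_a·(1 − s_a) for reaction times — with nonnegative
weights summing to 30, so the composite Σ c_a lies in [0, 30] and attains the
endpoints at uniformly extreme performance. Nonnegativity is enforced because
the [0, 30] guarantee fails without it.

**Missing assessments.** A subject missing some metrics is scored by
renormalizing the weights of the *present* assessments to the same total of
30, keeping all composites on one scale; at least 4 of 7 assessments
(`min_assessments`, configurable) are required, below which scoring raises an
error rather than extrapolating. A complete battery is unaffected by this
path (renormalization is then the identity).

## Weight fitting

Weights are chosen to maximize the Pearson correlation between the composite
and a 0–30 reference screener over a training cohort. Pearson correlation is
invariant to positive affine maps of the composite, so the search runs on the
unit simplex and the winner is rescaled to total 30 exactly. The simplex is
parameterized by softmax(z), z ∈ R^7, and −r is minimized by Nelder–Mead
(derivative-free; the objective is smooth in the interior but involves
per-subject weight renormalization under missingness). Starts: the equal-weight
point, each near-vertex point, and `n_restarts` (default 16) standard-normal
draws from a generator seeded by `config.seed`; the exact simplex vertices are
also evaluated directly, so the achieved correlation can never fall below the
best single assessment. The best start wins, ties going to the earlier one;
each restart stops when the objective improves by less than `tolerance`
(default 1e-8) or after 10,000 evaluations. Identical seed and cohort give
bit-identical weights.

`grid_oracle` enumerates every weight vector on a simplex lattice at a given
resolution and returns the argmax. It is deliberately slow and obviously
correct, and serves as the independent check on the optimizer in the tests
(exhaustive at fine resolution for ≤ 4 assessments, coarse for 7).

## Validation statistics

* **Dichotomization:** SLUMS ≤ 20 → dementia, ≥ 21 → control; physician
  labels binarize moderate + severe → impaired.
* **ROC:** lower composite = impaired, so a subject is called positive when
  the score falls *below* a threshold. Thresholds sit at midpoints between
  consecutive distinct scores plus two sentinels, so tied scores can never
  straddle a threshold; sensitivity/specificity are strict-inequality counts.
  AUC is the trapezoid over (1 − specificity, sensitivity), which equals the
  Mann–Whitney rank statistic P(impaired < healthy) + ½P(tie); both are
  implemented and cross-checked. The reported operating point maximizes
  Youden's J = sens + spec − 1, ties resolved toward higher specificity, then
  lower threshold.
* **t-tests:** pooled-variance two-sided Student's t by default (Welch behind
  `equal_var=False`), computable either from raw groups or from summary
  statistics alone (`ttest_from_summary`), the two agreeing to 1e-10 on
  groups constructed to have exactly the given moments.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — and
only that. One latent cognitive-status factor θ ~ N(0, 1) drives everything:

    raw_a = μ_a + σ_a (±λ_a θ + √(1 − λ_a²) ε),   ε ~ N(0, 1)

with the sign flipped for reaction times so higher θ always means better
cognition, then clamped to physical ranges (fractions to [0, 1], times and
rates floored at 0.01). The reference screener is
round(clamp(ref_mean + ref_sd (λ_ref θ + √(1 − λ_ref²) ε), 0, 30)).

**Calibrated truncation.** Several normative targets sit close to a bound —
immediate recall has mean 0.94 and SD 0.07, putting ~20% of a matching
normal's mass above 1 — so naive clamping would visibly bias the recovered
mean and shrink the SD. (μ_a, σ_a) are therefore *not* the targets
themselves: for each metric they are solved (closed-form clamped-normal
moments + root finding, cached) so that the post-clamp population mean and SD
equal the targets exactly. Parameter-recovery tests check sample moments at
n = 398 against the targets within 3 standard errors. Clamping still
attenuates the *correlations* of the near-bound metrics with θ by a few
hundredths; this is visible as recall/matrix correlations (~0.59) sitting
below the unclamped expectation λ_a·λ_ref = 0.646, and it lowers the achieved
composite correlation slightly below the idealized closed form.

**Defaults and what they mean.**

| parameter | default | meaning |
|---|---|---|
| `metric_means`/`metric_sds` | normative table | raw-metric calibration targets |
| `lambda_assessment` | 0.76 | loading of each metric on θ |
| `lambda_reference` | 0.85 | loading of the screener on θ |
| `ref_mean`, `ref_sd` | 20, 4 | screener placement on 0–30; keeps 0/30 clamping < 1% |
| `impaired_fraction` | 0 | share of subjects in the shifted component |
| `group_shift` | 0 (2.0 in the physician preset) | θ offset of the impaired component, latent-SD units |
| `missing_rate` | 0 | per-metric independent missingness (MCAR) |
| `age_mean`, `age_sd` | 70.2, 9.0 | cohort demographics (clipped at 50) |

The loadings are a joint calibration: 0.76 × 0.85 = 0.646 puts every
single-assessment correlation inside the moderate (.5–.7) band such
batteries show against the SLUMS, and the equal-weight composite correlation
λ_ref √(kλ²/(1 + (k−1)λ²)) = 0.809 matches the ~0.81 such optimized
composites achieve — both derivable from the closed form implemented in
`expected_composite_correlation`. The physician preset's `group_shift` = 2.0
reproduces a ~6-point composite gap between impaired and healthy groups
(≈ printed-gap / pooled-SD / corr(composite, θ)); its group sizes are
deterministic (round(n·impaired_fraction), severe = lowest θ tertile of the
impaired component), so an 18-subject cohort is exactly 9 healthy / 6
moderate / 3 severe.

**What the generator does not model** — and hence what passing tests do not
show about real data: age and practice effects, device differences,
multi-factor structure among the assessments (a single factor is the minimal
structure consistent with uniformly moderate cross-correlations), informative
missingness, and non-Gaussian tails beyond the truncation itself.

## Numerical choices and limitations

* Optimization tolerance 1e-8 on the objective, 10,000-evaluation cap per
  restart; at the default problem sizes a full 16-restart fit at n = 5000
  takes a few seconds.
* The moment-matching root-solve is tolerance 1e-12 and cached per
  (mean, SD, bounds).
* Degenerate inputs fail loudly: all-zero or negative weights, constant
  correlation margins, one-class ROC labels, out-of-range reference scores
  and incomplete batteries each raise a dedicated exception.
* Analyses use n = 5000 for weight fitting and closed-form comparisons
  (Monte-Carlo SE of r ≈ 0.005 there) and the study-sized cohorts
  (398/84/51/35/18) elsewhere.
* Fitted weights are noisy at realistic cohort sizes: at n = 84 the
  per-assessment weights vary widely across seeds even though the achieved
  correlation is stable. The package reports the train/held-out split as an
  overfitting check but deliberately implements no regularization or
  cross-validated selection.
* Real-cohort statistics (e.g. a normative composite mean near 22 with SD
  near 3, or specific published sensitivity/specificity pairs) depend on the
  true joint distribution of the battery and are not bit-reproducible from
  simulation; the pipeline reproduces their calibrated-simulation analogs and
  the exact summary-statistic computations (e.g. the pooled t-test on the
  printed physician-substudy moments).
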