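#!/usr/bin/env python
"""Validate the fitted composite on screener and physician cohorts.

Loads results/model.json (run 02_fit_weights.py first), then:

* correlates the composite and each assessment with simulated SLUMS, MMSE
  and MoCA cohorts at the study's cohort sizes (84 / 51 / 35);
* on the SLUMS cohort, dichotomizes at the 20/21 cutoff and reports the
  ROC AUC and the Youden operating point (sensitivity/specificity);
* on the physician substudy (n=18, 9 impaired), runs the two-sample t-test
  on composite scores and the physician-label ROC.

Writes results/validation_<cohort>.json for each comparison.
"""

from pathlib import Path

import numpy as np

from cogscore import (
    GeneratorConfig,
    binarize_physician,
    simulate_comparison,
    simulate_physician_substudy,
    validate_model,
)
from cogscore.io import model_from_json, write_artifact
from cogscore.validation import (
    auc,
    composite_scores,
    roc_points,
    two_sample_ttest,
    youden_operating_point,
)

SEED = 20262
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = model_from_json(OUT / "model.json")

    for reference, n, seed in (("slums", 84, SEED), ("mmse", 51, SEED + 1), ("moca", 35, SEED + 2)):
        cohort = simulate_comparison(GeneratorConfig(n=n), seed=seed, reference=reference)
        report = validate_model(cohort.subjects, model, reference=reference)
        corr = report["correlations"]
        line = f"{reference.upper():5s} n={n:3d}  composite r = {corr['composite']:.3f}"
        if "auc" in report:
            op = report["operating_point"]
            line += (
                f"  AUC = {report['auc']:.3f}  sens = {100 * op['sensitivity']:.0f}%"
                f"  spec = {100 * op['specificity']:.0f}%"
            )
        print(line)
        write_artifact(OUT / f"validation_{reference}.json", report, seed=seed, config=model.weights)

    cohort = simulate_physician_substudy(
        GeneratorConfig(n=18, impaired_fraction=0.5, group_shift=2.0), seed=SEED + 3
    )
    comp = composite_scores(cohort.subjects, model)
    labels = [binarize_physician(s.physician_label) for s in cohort.subjects]
    imp = comp[np.array(labels) == "impaired"]
    hea = comp[np.array(labels) == "healthy"]
    tt = two_sample_ttest(imp, hea)
    curve = roc_points(comp, labels)
    thr, sens, spec = youden_operating_point(curve)
    print(
        f"PHYS  n= 18  impaired {tt.group_means[0]:.1f} (SD {tt.group_sds[0]:.1f}) vs "
        f"healthy {tt.group_means[1]:.1f} (SD {tt.group_sds[1]:.1f}); "
        f"t = {tt.t_statistic:.2f}, p = {tt.p_value:.2g}; "
        f"AUC = {auc(curve):.3f}, sens = {100 * sens:.0f}%, spec = {100 * spec:.0f}%"
    )
    write_artifact(
        OUT / "validation_physician.json",
        {
            "group_comparison": {
                "impaired_mean": tt.group_means[0],
                "healthy_mean": tt.group_means[1],
                "impaired_sd": tt.group_sds[0],
                "healthy_sd": tt.group_sds[1],
                "ns": list(tt.group_ns),
                "t": tt.t_statistic,
                "p": tt.p_value,
            },
            "auc": auc(curve),
            "operating_point": {"threshold": thr, "sensitivity": sens, "specificity": spec},
        },
        seed=SEED + 3,
        config=model.weights,
    )


if __name__ == "__main__":
    main()
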