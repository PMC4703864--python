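"""Sensitivity/specificity of the SS-score classifier and confounder checks.

Scores the independent validation cohorts (200 controls, 19 cases) against
the reference profiles discovered in 02, reports the confusion summary, and
runs the nonparametric confounder checks (sex/age cohort composition;
score vs sex, age and batch within controls). Writes the per-sample score
table and a validation summary to results/.

Run after 02: python analysis/03_validate_classifier.py
"""

import json
from pathlib import Path

import pandas as pd

from episig import (
    Config,
    confounder_checks,
    evaluate_cohort,
    read_beta_matrix,
    read_sample_sheet,
    read_signature,
    score_cohort,
    scores_to_frame,
)

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    config = Config(seed=1)
    signature, profiles = read_signature(SCRATCH / "signature.tsv")
    frames = []
    summaries = {}
    for label, betas_file, sheet_file in (
        ("controls", "validation_controls.tsv", "validation_controls.csv"),
        ("cases", "validation_cases.tsv", "validation_cases.csv"),
    ):
        matrix = read_beta_matrix(SCRATCH / betas_file)
        sheet = read_sample_sheet(SCRATCH / sheet_file)
        results, failures = score_cohort(matrix, profiles, config)
        if failures:
            raise RuntimeError(f"unscorable samples: {failures}")
        report = evaluate_cohort(results, sheet)
        df = scores_to_frame(results)
        df.insert(1, "cohort", label)
        frames.append(df)
        summaries[label] = report.to_dict()
        print(
            f"{label}: n={len(results)}, scores "
            f"[{df['score'].min():+.3f}, {df['score'].max():+.3f}], "
            f"sensitivity={report.sensitivity:.3f} specificity={report.specificity:.3f}"
        )

    scores = pd.concat(frames, ignore_index=True)
    scores.to_csv(RESULTS / "03_validation_scores.csv", index=False)

    # confounders on the control cohort (plus cohort composition tests on
    # the discovery sheet)
    disc_sheet = read_sample_sheet(SCRATCH / "discovery_samples.csv")
    ctrl_matrix = read_beta_matrix(SCRATCH / "validation_controls.tsv")
    ctrl_sheet = read_sample_sheet(SCRATCH / "validation_controls.csv")
    ctrl_results, _ = score_cohort(ctrl_matrix, profiles, config)
    composition = confounder_checks(None, disc_sheet)
    within = confounder_checks(ctrl_results, ctrl_sheet)
    checks = pd.concat([composition, within], ignore_index=True)
    checks.to_csv(RESULTS / "03_confounders.csv", index=False)
    print("confounder checks (raw p):")
    for row in checks.itertuples():
        print(f"  {row.covariate:32s} {row.test:18s} p={row.p:.3f}")

    with open(RESULTS / "03_validation.json", "w") as fh:
        json.dump(
            {
                "specificity": summaries["controls"]["specificity"],
                "sensitivity": summaries["cases"]["sensitivity"],
                "controls": summaries["controls"],
                "cases": summaries["cases"],
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
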