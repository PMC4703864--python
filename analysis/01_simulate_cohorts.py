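"""Simulate the discovery cohort and validation cohorts.

Generates a 10,000-CpG discovery study with the target design — 19 cases
(one family of three) vs 53 controls, 1,000 signal CpGs with mean beta loss
0.25 and a 99.3% loss / 0.7% gain split — plus an independent 200-sample
control cohort and a 19-sample case cohort for validation. Matrices are
large and go to scratch/analysis/; a small design summary goes to results/.

Run from the repository root: python analysis/01_simulate_cohorts.py
"""

import json
from pathlib import Path

from episig import (
    generate_discovery_study,
    generate_validation_cohort,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)
from episig.synthetic_data import SimulationParams

SEED = 1
SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    params = SimulationParams(seed=SEED)
    matrix, sheet, annotation, truth = generate_discovery_study(params)

    write_beta_matrix(
        matrix, SCRATCH / "discovery_betas.tsv",
        detection_p_path=SCRATCH / "discovery_detection_p.tsv",
    )
    write_sample_sheet(sheet, SCRATCH / "discovery_samples.csv")
    write_probe_annotation(annotation, SCRATCH / "annotation.tsv")
    truth.signal.to_csv(SCRATCH / "truth_signal.tsv", sep="\t", index_label="probe_id")

    vctrl, vctrl_sheet = generate_validation_cohort(params, truth, "control", 200, seed=20001)
    vcase, vcase_sheet = generate_validation_cohort(params, truth, "case", 19, seed=20002)
    write_beta_matrix(vctrl, SCRATCH / "validation_controls.tsv")
    write_sample_sheet(vctrl_sheet, SCRATCH / "validation_controls.csv")
    write_beta_matrix(vcase, SCRATCH / "validation_cases.tsv")
    write_sample_sheet(vcase_sheet, SCRATCH / "validation_cases.csv")

    n_loss = int((truth.signal["direction"] == "loss").sum())
    summary = {
        "seed": SEED,
        "n_cpgs": params.n_cpgs,
        "n_signal": params.n_signal,
        "n_signal_loss": n_loss,
        "mean_true_shift": round(float(truth.signal["true_shift"].mean()), 4),
        "discovery": {"cases": 19, "controls": 53, "case_family_size": 3},
        "validation": {"controls": 200, "cases": 19},
    }
    with open(RESULTS / "01_simulation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"discovery matrix {matrix.shape[0]} CpGs x {matrix.shape[1]} samples")
    print(f"signal CpGs: {params.n_signal} ({n_loss} loss / {params.n_signal - n_loss} gain), "
          f"mean |shift| {summary['mean_true_shift']}")
    print(f"validation cohorts: 200 controls, 19 cases -> {SCRATCH}")


if __name__ == "__main__":
    main()
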