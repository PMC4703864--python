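"""Probe filtering and episignature discovery on the simulated study.

Reads the cohort written by 01_simulate_cohorts.py, removes SNP-affected,
cross-reactive and detection-failed probes, runs the three-trial
Mann-Whitney derivation with Bonferroni correction and the 0.20
effect-size filter, builds the median reference profiles, and clusters the
72 discovery samples over the signature CpGs. Writes the signature (with
profiles) to scratch/analysis/ and a discovery summary to results/.

Run after 01: python analysis/02_discover_signature.py
"""

import json
from pathlib import Path

from episig import (
    Config,
    apply_probe_filters,
    build_reference_profiles,
    derive_signature,
    hierarchical_clustering,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_signature,
)
from episig.evaluation import linkage_to_newick

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    config = Config(seed=1)
    matrix = read_beta_matrix(
        SCRATCH / "discovery_betas.tsv",
        detection_p_path=SCRATCH / "discovery_detection_p.tsv",
    )
    sheet = read_sample_sheet(SCRATCH / "discovery_samples.csv")
    annotation = read_probe_annotation(SCRATCH / "annotation.tsv")

    filtered, report = apply_probe_filters(matrix, annotation, config)
    print(
        f"probe filter: {report.n_input} -> {report.n_retained} retained "
        f"(SNP {report.n_removed_snp}, cross-reactive "
        f"{report.n_removed_cross_reactive}, detection {report.n_removed_detection})"
    )

    signature = derive_signature(filtered, sheet, config)
    split = signature.direction_split()
    print(
        f"signature: {len(signature)} CpGs, {split['loss']}% loss / "
        f"{split['gain']}% gain (Bonferroni m={signature.m}, "
        f"{signature.n_trials} trials)"
    )

    profiles = build_reference_profiles(filtered, sheet, signature)
    write_signature(signature, SCRATCH / "signature.tsv", profiles=profiles, config=config)

    clustering = hierarchical_clustering(filtered, signature, sheet)
    (SCRATCH / "discovery_tree.nwk").write_text(linkage_to_newick(clustering))
    print(f"hierarchical clustering separates cases from controls: "
          f"{clustering.separates_groups}")

    summary = {
        "filter": {k: v for k, v in report.to_dict().items() if k.startswith("n_")},
        "signature_size": len(signature),
        "direction_counts": signature.direction_counts(),
        "direction_split_percent": split,
        "bonferroni_m": signature.m,
        "n_trials": signature.n_trials,
        "clustering_separates_groups": clustering.separates_groups,
    }
    with open(RESULTS / "02_discovery.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
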