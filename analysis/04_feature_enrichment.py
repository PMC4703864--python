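"""Genomic-feature distribution of signature CpGs versus the background.

Compares the signature CpG set against the filtered (analyzable) probe set
across the annotation schemes — RefSeq gene group, CpG-island relation,
enhancer, DHS, DMR class and regulatory feature — with a two-sided
hypergeometric test per category and Benjamini-Hochberg adjustment within
each scheme. Writes the combined table to results/.

Run after 02: python analysis/04_feature_enrichment.py
"""

from pathlib import Path

import pandas as pd

from episig import feature_distribution, read_beta_matrix, read_probe_annotation, read_signature
from episig.annotation_enrichment import SCHEMES
from episig.probe_filter import apply_probe_filters
from episig import Config, read_sample_sheet

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    signature, _ = read_signature(SCRATCH / "signature.tsv")
    matrix = read_beta_matrix(
        SCRATCH / "discovery_betas.tsv",
        detection_p_path=SCRATCH / "discovery_detection_p.tsv",
    )
    annotation = read_probe_annotation(SCRATCH / "annotation.tsv")
    filtered, _ = apply_probe_filters(matrix, annotation, Config(seed=1))
    background = filtered.probe_ids

    tables = []
    for scheme in SCHEMES:
        dist = feature_distribution(signature, background, annotation, scheme)
        t = dist.table.copy()
        t.insert(0, "scheme", scheme)
        tables.append(t)
    combined = pd.concat(tables, ignore_index=True)
    combined.to_csv(RESULTS / "04_enrichment.csv", index=False)

    print(
        f"compared {len(signature)} signature CpGs against "
        f"{len(background)} background probes over {len(SCHEMES)} schemes"
    )
    notable = combined[combined["q_bh"] < 0.05]
    if len(notable):
        print("categories at q_BH < 0.05:")
        for row in notable.itertuples():
            print(
                f"  {row.scheme}/{row.category}: {row.pct_background:.1f}% -> "
                f"{row.pct_signature:.1f}% (fold {row.fold:.2f}, q={row.q_bh:.2e})"
            )
    else:
        print("no category reaches q_BH < 0.05 (annotation flags are drawn "
              "independently of signal status in this simulation)")


if __name__ == "__main__":
    main()
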