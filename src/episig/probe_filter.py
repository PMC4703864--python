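"""Probe exclusion: polymorphic, cross-reactive and poorly detected probes.

Probes are removed in a fixed order purely for report bookkeeping (each probe
is counted under the first rule that removes it); the retained set itself is
order-independent:

1. SNP-affected probes — a polymorphism at the interrogated C or G, at the
   single-base-extension position, or within 10 bases of the query site,
   whenever the minor-allele frequency reaches the configured threshold.
   A flagged probe with unknown MAF is removed (conservative).
2. Cross-reactive probes — sequences aligning to multiple genomic positions
   at >=90% identity, consumed as a manifest flag.
3. Detection failures — probes with any missing beta or any detection
   p-value above ``detection_p_max`` in any sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_types import BetaMatrix, Config, ProbeAnnotation, ValidationError

__all__ = ["FilterReport", "apply_probe_filters"]


@dataclass
class FilterReport:
    n_input: int
    n_removed_snp: int
    n_removed_cross_reactive: int
    n_removed_detection: int
    n_retained: int
    removed_snp: list[str] = field(default_factory=list)
    removed_cross_reactive: list[str] = field(default_factory=list)
    removed_detection: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_snp
            + self.n_removed_cross_reactive
            + self.n_removed_detection
        )
        if total != self.n_input:
            raise ValidationError("filter report counts do not sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_snp": self.n_removed_snp,
            "n_removed_cross_reactive": self.n_removed_cross_reactive,
            "n_removed_detection": self.n_removed_detection,
            "n_retained": self.n_retained,
            "removed_snp": self.removed_snp,
            "removed_cross_reactive": self.removed_cross_reactive,
            "removed_detection": self.removed_detection,
        }


def apply_probe_filters(
    matrix: BetaMatrix, annotation: ProbeAnnotation, config: Config
) -> tuple[BetaMatrix, FilterReport]:
    """Return the filtered matrix and a per-rule removal report."""
    probes = matrix.probe_ids
    missing_ann = probes.difference(annotation.probe_ids)
    if len(missing_ann):
        raise ValidationError(
            f"{len(missing_ann)} probes missing from annotation, e.g. "
            f"{missing_ann[:5].tolist()}"
        )
    ann = annotation.data.loc[probes]

    snp_flagged = (
        ann["snp_flag_cg"] | ann["snp_flag_extension"] | ann["snp_flag_10bp"]
    ).to_numpy()
    maf = ann["snp_maf"].to_numpy(dtype=float)
    # unknown MAF on a flagged probe is treated as exceeding the threshold
    maf_hit = np.isnan(maf) | (maf >= config.maf_threshold)
    snp_mask = snp_flagged & maf_hit

    cross_mask = ann["cross_reactive"].to_numpy() & ~snp_mask

    vals = matrix.betas.to_numpy()
    detect_bad = np.isnan(vals).any(axis=1)
    if matrix.detection_p is not None:
        detect_bad |= (
            matrix.detection_p.to_numpy() > config.detection_p_max
        ).any(axis=1)
    detect_mask = detect_bad & ~snp_mask & ~cross_mask

    keep = ~(snp_mask | cross_mask | detect_mask)
    if not keep.any():
        raise ValidationError("no probes retained after filtering")

    report = FilterReport(
        n_input=len(probes),
        n_removed_snp=int(snp_mask.sum()),
        n_removed_cross_reactive=int(cross_mask.sum()),
        n_removed_detection=int(detect_mask.sum()),
        n_retained=int(keep.sum()),
        removed_snp=probes[snp_mask].tolist(),
        removed_cross_reactive=probes[cross_mask].tolist(),
        removed_detection=probes[detect_mask].tolist(),
    )
    return matrix.subset_probes(probes[keep]), report
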