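"""Correlation-score classification against median reference profiles.

The score for a sample is r(B_sig, m_case) - r(B_sig, m_control), where
B_sig is the sample's beta vector over the signature CpGs, m_case and
m_control are the per-CpG median betas of the discovery cases and controls,
and r is the Pearson correlation on untransformed betas. A positive score
(more similar to the case profile) is called 'SS', otherwise 'not_SS'; an
exact tie at the threshold is called 'not_SS' with a warning — conservative
for a diagnostic claim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_types import (
    BetaMatrix,
    Config,
    ReferenceProfiles,
    SampleSheet,
    SignatureSet,
    ValidationError,
)

logger = logging.getLogger("episig")

__all__ = [
    "ScoreResult",
    "build_reference_profiles",
    "ss_score",
    "score_cohort",
    "scores_to_frame",
]


@dataclass
class ScoreResult:
    sample_id: str
    r_case: float
    r_control: float
    score: float
    call: str  # 'SS' | 'not_SS'
    n_cpgs_used: int


def build_reference_profiles(
    matrix: BetaMatrix, sheet: SampleSheet, signature: SignatureSet
) -> ReferenceProfiles:
    """Per-CpG median betas over discovery cases and controls.

    Medians use the midpoint convention for even counts (numpy default).
    """
    missing = signature.probe_ids.difference(matrix.probe_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} signature probes absent from matrix, e.g. "
            f"{missing[:5].tolist()}"
        )
    cases = sheet.case_ids
    controls = sheet.control_ids
    if not cases or not controls:
        raise ValidationError("need at least one case and one control")
    block = matrix.betas.loc[signature.probe_ids]
    m_case = block[cases].median(axis=1).rename("m_case")
    m_control = block[controls].median(axis=1).rename("m_control")
    return ReferenceProfiles(m_case=m_case, m_control=m_control)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValidationError("constant vector in Pearson correlation")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def ss_score(
    sample_betas: pd.Series, profiles: ReferenceProfiles, config: Config
) -> ScoreResult:
    """Score one sample against the two reference profiles.

    Signature CpGs missing from the sample are dropped pairwise from both
    correlations; coverage below ``config.min_coverage`` of the signature
    is an error.
    """
    aligned = sample_betas.reindex(profiles.probe_ids)
    mask = aligned.notna().to_numpy()
    n_used = int(mask.sum())
    coverage = n_used / len(profiles)
    if coverage < config.min_coverage:
        raise ValidationError(
            f"sample {sample_betas.name!r} covers {coverage:.1%} of the "
            f"signature (minimum {config.min_coverage:.0%})"
        )
    b = aligned.to_numpy(dtype=float)[mask]
    if np.ptp(b) == 0:
        raise ValidationError(
            f"sample {sample_betas.name!r} is constant over the signature; "
            "correlation undefined"
        )
    r_case = _pearson(b, profiles.m_case.to_numpy()[mask])
    r_control = _pearson(b, profiles.m_control.to_numpy()[mask])
    score = r_case - r_control
    if score == config.score_threshold:
        logger.warning(
            "sample %r scores exactly at the threshold; calling not_SS",
            sample_betas.name,
        )
    call = "SS" if score > config.score_threshold else "not_SS"
    return ScoreResult(
        sample_id=str(sample_betas.name),
        r_case=r_case,
        r_control=r_control,
        score=score,
        call=call,
        n_cpgs_used=n_used,
    )


def score_cohort(
    matrix: BetaMatrix, profiles: ReferenceProfiles, config: Config
) -> tuple[list[ScoreResult], dict[str, str]]:
    """Score every sample; per-sample failures are collected, not fatal.

    Returns (results in input sample order, {sample_id: error message}).
    """
    results: list[ScoreResult] = []
    failures: dict[str, str] = {}
    common = profiles.probe_ids.intersection(matrix.probe_ids)
    block = matrix.betas.loc[common]
    for sid in matrix.sample_ids:
        try:
            results.append(ss_score(block[sid], profiles, config))
        except ValidationError as exc:
            failures[str(sid)] = str(exc)
            logger.warning("could not score sample %r: %s", sid, exc)
    return results, failures


def scores_to_frame(results: list[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "r_case": r.r_case,
                "r_control": r.r_control,
                "score": r.score,
                "call": r.call,
                "n_cpgs_used": r.n_cpgs_used,
            }
            for r in results
        ]
    )
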