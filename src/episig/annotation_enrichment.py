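"""Genomic-feature distribution of signature CpGs versus the background.

For a chosen annotation scheme (RefSeq gene group, CpG-island relation,
enhancer, DHS, DMR class, regulatory feature), compares category percentages
between the signature and the analyzable background probe set, with a
two-sided hypergeometric test per category (the signature is a subset drawn
from the background). Multi-valued manifest entries (';'-separated) count a
probe once per distinct category it carries, so multi-valued percentages
need not sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import ProbeAnnotation, SignatureSet, ValidationError

__all__ = ["FeatureDistribution", "feature_distribution", "hypergeom_two_sided"]

SCHEMES = (
    "refgene_group",
    "island_relation",
    "enhancer",
    "dhs",
    "dmr_class",
    "regulatory_feature",
)
BOOLEAN_SCHEMES = {"enhancer": ("flagged", "not_flagged"), "dhs": ("flagged", "not_flagged")}


@dataclass
class FeatureDistribution:
    scheme: str
    table: pd.DataFrame  # category, n_background, pct_background, n_signature,
    #                      pct_signature, fold, p, q_bh
    n_background: int
    n_signature: int


def hypergeom_two_sided(k: int, n_draw: int, k_total: int, n_total: int) -> float:
    """Two-sided hypergeometric p by the minimum-likelihood rule.

    Sums P(X = j) over all j whose point probability does not exceed that of
    the observed count k (the convention of R's fisher.test), for X ~
    Hypergeom(n_total, k_total, n_draw).
    """
    rv = stats.hypergeom(n_total, k_total, n_draw)
    support = np.arange(max(0, n_draw - (n_total - k_total)), min(n_draw, k_total) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(k)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def _category_members(values: pd.Series) -> dict[str, set]:
    """probe sets per category; ';'-separated entries are multi-valued."""
    members: dict[str, set] = {}
    for pid, raw in values.items():
        if pd.isna(raw):
            cats = ["none"]
        else:
            cats = sorted({c.strip() for c in str(raw).split(";") if c.strip()}) or ["none"]
        for c in cats:
            members.setdefault(c, set()).add(pid)
    return members


def feature_distribution(
    signature: SignatureSet | pd.Index,
    background_ids: pd.Index,
    annotation: ProbeAnnotation,
    scheme: str,
) -> FeatureDistribution:
    """Counts, percentages, folds and hypergeometric p per category."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    sig_ids = signature.probe_ids if isinstance(signature, SignatureSet) else pd.Index(signature)
    background_ids = pd.Index(background_ids)
    outside = sig_ids.difference(background_ids)
    if len(outside):
        raise ValidationError(
            f"{len(outside)} signature probes absent from background, e.g. "
            f"{outside[:5].tolist()}"
        )
    missing = background_ids.difference(annotation.probe_ids)
    if len(missing):
        raise ValidationError(f"{len(missing)} background probes not annotated")

    n_bg, n_sig = len(background_ids), len(sig_ids)
    sig_set = set(sig_ids)
    if scheme in BOOLEAN_SCHEMES:
        flags = annotation.data.loc[background_ids, scheme].astype(bool)
        yes, no = BOOLEAN_SCHEMES[scheme]
        members = {
            yes: set(flags.index[flags]),
            no: set(flags.index[~flags]),
        }
    else:
        members = _category_members(annotation.data.loc[background_ids, scheme])

    rows = []
    for cat in sorted(members):
        bg_hits = len(members[cat])
        sig_hits = len(members[cat] & sig_set)
        pct_bg = 100.0 * bg_hits / n_bg
        pct_sig = 100.0 * sig_hits / n_sig if n_sig else float("nan")
        fold = pct_sig / pct_bg if pct_bg > 0 else float("inf")
        p = hypergeom_two_sided(sig_hits, n_sig, bg_hits, n_bg)
        rows.append(
            {
                "category": cat,
                "n_background": bg_hits,
                "pct_background": pct_bg,
                "n_signature": sig_hits,
                "pct_signature": pct_sig,
                "fold": fold,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q_bh"] = _bh_adjust(table["p"].to_numpy()) if len(table) else []
    return FeatureDistribution(
        scheme=scheme, table=table, n_background=n_bg, n_signature=n_sig
    )
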