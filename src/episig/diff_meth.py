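"""Episignature derivation: family-robust three-trial Mann-Whitney testing.

When the case cohort contains families, each trial combines all non-familial
cases with exactly one representative per family (one trial per combination
of representatives; three trials for a single family of three). Every probe
is tested per trial with a two-sided Mann-Whitney U test, Bonferroni-adjusted
over the number of probes tested; the signature retains CpGs that are
significant in *all* trials, show at least the configured absolute
group-mean beta difference in all trials, and shift in a consistent
direction. Direction 'loss' means cases are hypomethylated (delta < 0).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import BetaMatrix, Config, SampleSheet, SignatureSet, ValidationError

logger = logging.getLogger("episig")

__all__ = [
    "TrialDesign",
    "build_trials",
    "mann_whitney_test",
    "bonferroni_adjust",
    "derive_signature",
]

EXACT_MIN_N = 8  # below this per-group size the exact null is enumerated


@dataclass
class TrialDesign:
    """Case-sample sets per trial plus the shared control set."""

    trials: list[list[str]]
    controls: list[str]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_trials(sheet: SampleSheet) -> TrialDesign:
    """One trial per combination of one representative per case family.

    Without case families this is a single trial of all cases. Case families
    of size one are treated as non-familial (with a warning, handled by
    :meth:`SampleSheet.case_families`).
    """
    cases = sheet.case_ids
    controls = sheet.control_ids
    if not cases or not controls:
        raise ValidationError("need at least one case and one control")
    families = sheet.case_families()
    familial = {m for members in families.values() for m in members}
    singles = [c for c in cases if c not in familial]
    if not families:
        return TrialDesign(trials=[list(cases)], controls=controls)
    trials = [
        singles + list(reps)
        for reps in itertools.product(*families.values())
    ]
    return TrialDesign(trials=trials, controls=controls)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (midranks for ties)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n1+n2, n1) group assignments
    of the pooled midranks; the null distribution of U is symmetric about
    n1*n2/2, so two-sided means |U - n1*n2/2| >= |u_obs - n1*n2/2|."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid) - 1e-9
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mid) >= dev:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for one CpG.

    Returns (U, p) where U is the statistic for ``x`` computed with
    midranks. With both group sizes >= 8 the p-value uses the normal
    approximation with tie and continuity corrections; smaller designs are
    handled by exact enumeration over all group assignments (valid under
    ties, unlike the textbook exact tables). p is clamped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty group in Mann-Whitney test")
    u = _u_statistic(x, y)
    if min(x.size, y.size) >= EXACT_MIN_N:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    else:
        p = _exact_two_sided_p(x, y, u)
    return float(u), min(max(p, np.nextafter(0, 1)), 1.0)


def bonferroni_adjust(p, m: int):
    """q = min(1, m * p)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


def _trial_test(case_block: np.ndarray, ctrl_block: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-probe U and two-sided p for one trial.

    Blocks are (n_probes, n_samples). Uses the asymptotic branch when both
    groups have >= EXACT_MIN_N samples, otherwise falls back to the exact
    per-probe test.
    """
    n1, n2 = case_block.shape[1], ctrl_block.shape[1]
    if min(n1, n2) >= EXACT_MIN_N:
        res = stats.mannwhitneyu(
            case_block, ctrl_block, axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    out_u = np.empty(case_block.shape[0])
    out_p = np.empty(case_block.shape[0])
    for i in range(case_block.shape[0]):
        out_u[i], out_p[i] = mann_whitney_test(case_block[i], ctrl_block[i])
    return out_u, out_p


def derive_signature(
    matrix: BetaMatrix, sheet: SampleSheet, config: Config
) -> SignatureSet:
    """Run the full three-trial derivation on a probe-filtered matrix.

    Retention requires, in every trial: Bonferroni-adjusted q < alpha
    (m = number of probes tested) and |mean_case - mean_control| >=
    effect_size_min, with a consistent sign of the difference across
    trials. Probes with missing betas are dropped beforehand with a
    warning (filtering is expected upstream).
    """
    design = build_trials(sheet)
    betas = matrix.betas
    has_nan = betas.isna().any(axis=1)
    if has_nan.any():
        logger.warning(
            "dropping %d probes with missing betas before testing", int(has_nan.sum())
        )
        betas = betas[~has_nan]
    m = len(betas)
    if m == 0:
        raise ValidationError("no probes to test")
    ctrl = betas[design.controls].to_numpy()
    if ctrl.shape[1] < 2:
        raise ValidationError("fewer than 2 control samples")

    per_trial: dict[str, np.ndarray] = {}
    deltas = np.empty((m, design.n_trials))
    qs = np.empty((m, design.n_trials))
    mean_cases = np.empty((m, design.n_trials))
    mean_ctrl = ctrl.mean(axis=1)
    for t, case_ids in enumerate(design.trials):
        case = betas[case_ids].to_numpy()
        if case.shape[1] < 2:
            raise ValidationError(f"fewer than 2 case samples in trial {t + 1}")
        u, p = _trial_test(case, ctrl)
        q = bonferroni_adjust(p, m)
        mc = case.mean(axis=1)
        deltas[:, t] = mc - mean_ctrl
        qs[:, t] = q
        mean_cases[:, t] = mc
        per_trial[f"U_trial{t + 1}"] = u
        per_trial[f"p_trial{t + 1}"] = p
        per_trial[f"q_trial{t + 1}"] = q
        per_trial[f"delta_trial{t + 1}"] = deltas[:, t]

    sig_all = (qs < config.alpha).all(axis=1)
    effect_all = (np.abs(deltas) >= config.effect_size_min).all(axis=1)
    consistent = (deltas > 0).all(axis=1) | (deltas < 0).all(axis=1)
    keep = sig_all & effect_all & consistent

    stats_df = pd.DataFrame(per_trial, index=betas.index)
    stats_df.insert(0, "direction", np.where(deltas.mean(axis=1) < 0, "loss", "gain"))
    stats_df.insert(1, "mean_case", mean_cases.mean(axis=1))
    stats_df.insert(2, "mean_control", mean_ctrl)
    stats_df.insert(3, "delta_beta", deltas.mean(axis=1))
    stats_df["n_significant_trials"] = (qs < config.alpha).sum(axis=1)

    sig = SignatureSet(
        stats=stats_df[keep].copy(), m=m, n_trials=design.n_trials
    )
    if len(sig) == 0:
        logger.warning("derived signature is empty")
    return sig


def full_test_table(matrix: BetaMatrix, sheet: SampleSheet, config: Config
                    ) -> pd.DataFrame:
    """Per-probe test results for *all* probes (no retention filter)."""
    design = build_trials(sheet)
    betas = matrix.betas.dropna(axis=0)
    ctrl = betas[design.controls].to_numpy()
    m = len(betas)
    cols: dict[str, np.ndarray] = {}
    for t, case_ids in enumerate(design.trials):
        case = betas[case_ids].to_numpy()
        u, p = _trial_test(case, ctrl)
        cols[f"U_trial{t + 1}"] = u
        cols[f"p_trial{t + 1}"] = p
        cols[f"q_trial{t + 1}"] = bonferroni_adjust(p, m)
        cols[f"delta_trial{t + 1}"] = case.mean(axis=1) - ctrl.mean(axis=1)
    return pd.DataFrame(cols, index=betas.index)
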