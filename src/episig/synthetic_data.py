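"""Synthetic 450K-style methylation cohorts.

The generator emulates the statistical structure of a blood-methylation
case/control study: per-CpG baseline means drawn from a bimodal
(unmethylated/methylated) mixture, per-sample beta values drawn from a beta
distribution with that mean and a precision parameter kappa, a subset of
"signal" CpGs whose case-group mean is shifted (predominantly towards loss
of methylation), optional case families sharing a random effect, optional
additive logit-scale batch shifts, and a detection-p matrix with a small
rate of failed measurements.

Per-CpG shift magnitudes at signal probes follow a right-skewed
shifted-gamma distribution with mean ``delta_beta`` (``delta_beta`` is the
*mean* shift magnitude): most effects sit just above the minimum of
0.75*delta_beta and a tail reaches roughly twice the mean, mirroring the
skewed spread of measured 450K effect sizes above an absolute-difference
filter. A strictly constant shift would be doubly wrong: the case reference
profile would become an affine translation of the control profile over an
almost-all-loss signature (invisible to a Pearson-correlation classifier),
and case samples would be no more correlated with each other than with
controls (so cases could not cluster as a distinct group).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_types import (
    ANNOTATION_COLUMNS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "generate_discovery_study",
    "generate_validation_cohort",
]

# Rough 450K-manifest category frequencies used for the simulated annotation.
DEFAULT_ANNOTATION_RATES: dict = {
    "snp_flag_cg": 0.020,
    "snp_flag_extension": 0.010,
    "snp_flag_10bp": 0.025,
    "snp_maf_known": 0.90,       # fraction of flagged probes with a known MAF
    "cross_reactive": 0.060,
    "enhancer": 0.21,
    "dhs": 0.12,
    "refgene_group": {
        "TSS1500": 0.14, "TSS200": 0.12, "5'UTR": 0.12,
        "Body": 0.35, "3'UTR": 0.04, "intergenic": 0.23,
    },
    "island_relation": {
        "Island": 0.31, "N_Shore": 0.13, "S_Shore": 0.10,
        "N_Shelf": 0.05, "S_Shelf": 0.04, "OpenSea": 0.37,
    },
    "dmr_class": {"RDMR": 0.04, "cDMR": 0.02, "other": 0.05, "none": 0.89},
    "regulatory_feature": {
        "Promoter_Associated": 0.25, "Gene_Associated": 0.03,
        "NonGene_Associated": 0.02, "Unclassified": 0.12, "none": 0.58,
    },
}

MEAN_CLIP = (0.02, 0.98)  # generative means are clipped here before sampling
# per-CpG shift = delta * (SHIFT_MIN_FRAC + Gamma(shape, scale)); the gamma
# part has mean 0.25 so the overall mean is exactly delta
SHIFT_MIN_FRAC = 0.75
SHIFT_GAMMA_SHAPE = 2.0
SHIFT_GAMMA_SCALE = 0.125
SHIFT_MAX = 0.90          # keeps the shifted mean representable in (0, 1)


@dataclass
class SimulationParams:
    """Cohort-simulation settings.

    Defaults mirror the discovery design this pipeline targets: 19 cases
    (including one family of three) versus 53 controls, ~99.3% of true
    signal CpGs losing methylation in cases, a mean absolute beta shift of
    0.25 at signal CpGs, and beta-distributed per-sample noise with
    precision kappa=80 (a modelling choice: array betas at mid-range means
    then have s.d. ~0.055, typical of blood 450K replicates).
    """

    n_cpgs: int = 10_000
    n_signal: int = 1_000
    frac_loss: float = 0.993
    delta_beta: float = 0.25
    concentration: float = 80.0
    n_cases: int = 19
    n_controls: int = 53
    family_spec: tuple[int, float] | None = (3, 0.3)   # (family size, rho)
    batch_spec: tuple[int, float] | None = (2, 0.05)   # (n batches, logit shift)
    missing_rate: float = 0.001
    annotation_rates: dict = field(default_factory=lambda: dict(DEFAULT_ANNOTATION_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_loss <= 1:
            raise ValidationError("frac_loss must be in [0, 1]")
        if not 0 < self.delta_beta < 1:
            raise ValidationError("delta_beta must be in (0, 1)")
        if self.n_signal > self.n_cpgs:
            raise ValidationError("n_signal exceeds n_cpgs")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.family_spec is not None:
            size, rho = self.family_spec
            if size < 2 or not 0 <= rho < 1:
                raise ValidationError("family_spec must be (size>=2, 0<=rho<1)")
            if size > self.n_cases:
                raise ValidationError("family larger than case cohort")


@dataclass
class SimulationTruth:
    """Generative ground truth for a simulated study."""

    baseline_mean: pd.Series            # per-probe baseline mean, all probes
    signal: pd.DataFrame                # index probe_id; direction, true_shift
    params: SimulationParams

    @property
    def signal_probe_ids(self) -> pd.Index:
        return self.signal.index

    def case_means(self) -> pd.Series:
        """Generative per-probe means for the case group (clip applied)."""
        mu = self.baseline_mean.copy()
        sign = np.where(self.signal["direction"] == "loss", -1.0, 1.0)
        mu.loc[self.signal.index] = np.clip(
            mu.loc[self.signal.index] + sign * self.signal["true_shift"], *MEAN_CLIP
        )
        return mu


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _sample_betas(rng: np.random.Generator, means: np.ndarray, kappa: float) -> np.ndarray:
    """Beta draws with given means and precision; means clipped to MEAN_CLIP."""
    mu = np.clip(means, *MEAN_CLIP)
    return rng.beta(mu * kappa, (1.0 - mu) * kappa)


def _family_split(kappa: float, rho: float) -> tuple[float, float]:
    """Two-stage beta precisions giving within-family correlation rho while
    preserving the marginal variance mu(1-mu)/(kappa+1)."""
    if rho == 0:
        return np.inf, kappa
    kappa1 = (kappa + 1.0) / rho - 1.0
    kappa2 = kappa / (1.0 - rho)
    return kappa1, kappa2


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal array-like baseline: components concentrated near 0.1 and 0.9."""
    low = rng.random(n) < 0.5
    means = np.where(low, rng.beta(5.0, 45.0, n), rng.beta(45.0, 5.0, n))
    return np.clip(means, 0.03, 0.97)


def _draw_truth(params: SimulationParams) -> SimulationTruth:
    rng = _substream(params.seed, 1)
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(params.n_cpgs)], name="probe_id")
    baseline = pd.Series(_baseline_means(rng, params.n_cpgs), index=probe_ids)

    signal_ids = pd.Index(
        rng.choice(params.n_cpgs, size=params.n_signal, replace=False)
    ).sort_values()
    signal_ids = probe_ids[signal_ids]
    n_loss = int(round(params.frac_loss * params.n_signal))
    directions = np.array(["loss"] * n_loss + ["gain"] * (params.n_signal - n_loss))
    rng.shuffle(directions)
    shifts = params.delta_beta * (
        SHIFT_MIN_FRAC + rng.gamma(SHIFT_GAMMA_SHAPE, SHIFT_GAMMA_SCALE, params.n_signal)
    )
    shifts = np.minimum(shifts, SHIFT_MAX)
    # baselines at signal probes are redrawn from the component that leaves
    # room for the full shift: loss CpGs start methylated, gain CpGs start
    # unmethylated (methylation loss happens at normally methylated sites)
    lo, hi = MEAN_CLIP
    base_sig = np.where(
        directions == "loss",
        np.clip(rng.beta(45.0, 5.0, params.n_signal), shifts + lo + 0.01, 0.97),
        np.clip(rng.beta(5.0, 45.0, params.n_signal), 0.03, hi - shifts - 0.01),
    )
    baseline.loc[signal_ids] = base_sig
    signal = pd.DataFrame(
        {"direction": directions, "true_shift": shifts}, index=signal_ids
    )
    return SimulationTruth(baseline_mean=baseline, signal=signal, params=params)


def _simulate_samples(
    rng: np.random.Generator,
    params: SimulationParams,
    truth: SimulationTruth,
    sample_groups: list[str],
    family_members: list[bool],
    batches: np.ndarray | None,
    logit_offset: float = 0.0,
) -> np.ndarray:
    """Draw a (n_cpgs, n_samples) beta matrix.

    family_members flags samples (cases) sharing the single simulated family;
    they receive a common first-stage draw realizing correlation rho.
    ``params`` governs the noise model (it may differ from ``truth.params``,
    e.g. for a lower-noise validation tissue); ``truth`` fixes the means.
    """
    kappa = params.concentration
    n = len(sample_groups)
    n_cpgs = len(truth.baseline_mean)
    mu_control = truth.baseline_mean.to_numpy()
    mu_case = truth.case_means().to_numpy()

    fam_idx = [i for i, f in enumerate(family_members) if f]
    fam_mu = None
    if fam_idx and params.family_spec is not None:
        _, rho = params.family_spec
        kappa1, kappa2 = _family_split(kappa, rho)
        if np.isfinite(kappa1):
            fam_mu = _sample_betas(rng, mu_case, kappa1)  # shared family stage
        kappa_fam = kappa2
    out = np.empty((n_cpgs, n))
    for j, grp in enumerate(sample_groups):
        mu = mu_case if grp == "case" else mu_control
        kap = kappa
        if j in fam_idx and fam_mu is not None:
            mu, kap = fam_mu, kappa_fam
        if batches is not None or logit_offset:
            shift = (0.0 if batches is None else batches[j]) + logit_offset
            if shift:
                mu = _expit(_logit(np.clip(mu, *MEAN_CLIP)) + shift)
        out[:, j] = _sample_betas(rng, mu, kap)
    return out


def _batch_shifts(params: SimulationParams, n: int, first_batch: int = 0
                  ) -> tuple[np.ndarray | None, list[str]]:
    if params.batch_spec is None:
        return None, ["batch0"] * n
    n_batches, magnitude = params.batch_spec
    assignment = np.arange(n) % n_batches
    centered = assignment - (n_batches - 1) / 2.0
    labels = [f"batch{first_batch + a}" for a in assignment]
    return centered * magnitude, labels


def _detection_p(rng: np.random.Generator, shape: tuple[int, int], missing_rate: float
                 ) -> np.ndarray:
    p = rng.uniform(0.0, 0.005, shape)
    failed = rng.random(shape) < missing_rate
    p[failed] = rng.uniform(0.02, 0.5, int(failed.sum()))
    return p


def _simulate_annotation(params: SimulationParams, probe_ids: pd.Index
                         ) -> ProbeAnnotation:
    rng = _substream(params.seed, 2)
    rates = params.annotation_rates
    n = len(probe_ids)
    data = {}
    for flag in ("snp_flag_cg", "snp_flag_extension", "snp_flag_10bp", "cross_reactive",
                 "enhancer", "dhs"):
        data[flag] = rng.random(n) < rates[flag]
    flagged = data["snp_flag_cg"] | data["snp_flag_extension"] | data["snp_flag_10bp"]
    maf = np.full(n, np.nan)
    known = flagged & (rng.random(n) < rates["snp_maf_known"])
    # allele frequencies span rare to common so the MAF cutoff has bite
    maf[known] = rng.beta(0.4, 3.0, int(known.sum())) * 0.5
    data["snp_maf"] = maf
    for scheme in ("refgene_group", "island_relation", "dmr_class", "regulatory_feature"):
        cats = list(rates[scheme])
        probs = np.array([rates[scheme][c] for c in cats], dtype=float)
        data[scheme] = rng.choice(cats, size=n, p=probs / probs.sum())
    df = pd.DataFrame(data, index=probe_ids)[ANNOTATION_COLUMNS]
    return ProbeAnnotation(df)


def _demographics(rng: np.random.Generator, group: str, n: int
                  ) -> tuple[list[str], np.ndarray]:
    """Sex and age with discovery-cohort-like distributions (cases skew male
    and have a wider age spread)."""
    p_male = 11 / 19 if group == "case" else 24 / 53
    sexes = np.where(rng.random(n) < p_male, "M", "F").tolist()
    if group == "case":
        ages = rng.gamma(shape=1.11, scale=9.12, size=n)  # mean 10.1, sd 9.6
    else:
        ages = rng.gamma(shape=5.06, scale=2.13, size=n)  # mean 10.8, sd 4.8
    return sexes, np.clip(np.round(ages, 1), 0.5, None)


def generate_discovery_study(
    params: SimulationParams,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, SimulationTruth]:
    """Simulate a discovery cohort (cases incl. one optional family, controls).

    Fully reproducible from ``params.seed``; independent named substreams
    drive the truth, the annotation, the discovery samples and any later
    validation cohorts.
    """
    truth = _draw_truth(params)
    probe_ids = truth.baseline_mean.index
    annotation = _simulate_annotation(params, probe_ids)

    rng = _substream(params.seed, 3)
    n = params.n_cases + params.n_controls
    groups = ["case"] * params.n_cases + ["control"] * params.n_controls
    sample_ids = [f"case_{i+1:03d}" for i in range(params.n_cases)] + [
        f"ctrl_{i+1:03d}" for i in range(params.n_controls)
    ]
    family = [False] * n
    family_ids: list = [np.nan] * n
    if params.family_spec is not None:
        size, _ = params.family_spec
        for i in range(size):
            family[i] = True
            family_ids[i] = "fam1"

    batch_shift, batch_labels = _batch_shifts(params, n)
    betas = _simulate_samples(rng, params, truth, groups, family, batch_shift)
    dp = _detection_p(rng, betas.shape, params.missing_rate)

    matrix = BetaMatrix(
        pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        pd.DataFrame(dp, index=probe_ids, columns=sample_ids),
    )
    sex_case, age_case = _demographics(rng, "case", params.n_cases)
    sex_ctrl, age_ctrl = _demographics(rng, "control", params.n_controls)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": groups,
                "sex": sex_case + sex_ctrl,
                "age": np.concatenate([age_case, age_ctrl]),
                "batch": batch_labels,
                "family_id": family_ids,
                "tissue": "blood",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, sheet, annotation, truth


def generate_validation_cohort(
    params: SimulationParams,
    truth: SimulationTruth,
    group: str,
    n: int,
    seed: int | None = None,
    logit_offset: float = 0.0,
    tissue: str = "blood",
) -> tuple[BetaMatrix, SampleSheet]:
    """Draw n new independent samples from the same generative model.

    Samples carry a batch label distinct from every discovery batch. The
    optional ``logit_offset`` shifts all generative means on the logit scale
    (a crude tissue effect, e.g. for fibroblast-like cohorts).
    """
    if group not in ("case", "control"):
        raise ValidationError(f"group must be 'case' or 'control', got {group!r}")
    if not truth.baseline_mean.index.equals(
        pd.Index([f"cg{i:08d}" for i in range(params.n_cpgs)], name="probe_id")
    ):
        raise ValidationError("truth probe set incompatible with params.n_cpgs")
    key = 4 if group == "control" else 5
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _substream(params.seed, key, n)
    )
    groups = [group] * n
    betas = _simulate_samples(
        rng, params, truth, groups, [False] * n, None, logit_offset=logit_offset
    )
    dp = _detection_p(rng, betas.shape, params.missing_rate)
    prefix = "vcase" if group == "case" else "vctrl"
    sample_ids = [f"{prefix}_{i+1:04d}" for i in range(n)]
    probe_ids = truth.baseline_mean.index
    matrix = BetaMatrix(
        pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        pd.DataFrame(dp, index=probe_ids, columns=sample_ids),
    )
    sexes, ages = _demographics(rng, group, n)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": groups,
                "sex": sexes,
                "age": ages,
                "batch": "validation",
                "family_id": np.nan,
                "tissue": tissue,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, sheet
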