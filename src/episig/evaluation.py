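"""Cohort-level validation of a derived episignature.

Covers the confusion-matrix summary (sensitivity/specificity of the SS
call against the sample-sheet labels), unsupervised hierarchical clustering
of samples over the signature CpGs with a Pearson-correlation distance, and
nonparametric confounder checks (sex, age, batch, and any extra numeric or
categorical covariate such as externally estimated cell fractions — the
latter is a generic stand-in for a dedicated cell-composition analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .classifier import ScoreResult
from .core_types import BetaMatrix, SampleSheet, SignatureSet, ValidationError

logger = logging.getLogger("episig")

__all__ = [
    "EvalReport",
    "ClusteringResult",
    "evaluate_cohort",
    "hierarchical_clustering",
    "confounder_checks",
]


@dataclass
class EvalReport:
    n_case: int
    n_control: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    scores: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate_cohort(scores: list[ScoreResult], sheet: SampleSheet) -> EvalReport:
    """Confusion counts of SS calls against case/control truth labels."""
    rows = []
    for r in scores:
        if r.sample_id not in sheet.sample_ids:
            raise ValidationError(f"scored sample {r.sample_id!r} not in sheet")
        group = sheet.data.loc[r.sample_id, "group"]
        if group not in ("case", "control"):
            raise ValidationError(
                f"sample {r.sample_id!r} has no case/control truth label"
            )
        rows.append((r.sample_id, group, r.score, r.call))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "score", "call"])
    tp = int(((df["group"] == "case") & (df["call"] == "SS")).sum())
    fn = int(((df["group"] == "case") & (df["call"] != "SS")).sum())
    tn = int(((df["group"] == "control") & (df["call"] == "not_SS")).sum())
    fp = int(((df["group"] == "control") & (df["call"] != "not_SS")).sum())
    n_case, n_control = tp + fn, tn + fp
    return EvalReport(
        n_case=n_case,
        n_control=n_control,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / n_case if n_case else float("nan"),
        specificity=tn / n_control if n_control else float("nan"),
        scores=df,
    )


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]
    partition: pd.Series            # sample_id -> cluster {1, 2}
    separates_groups: bool | None   # None when no labels were supplied


def hierarchical_clustering(
    matrix: BetaMatrix,
    signature: SignatureSet,
    sheet: SampleSheet | None = None,
    method: str = "average",
) -> ClusteringResult:
    """Cluster samples over signature CpGs with distance 1 - Pearson r.

    The tree is cut at k=2; when a sheet with case/control labels is given,
    ``separates_groups`` records whether the two clusters match the labels
    (up to swapping cluster names).
    """
    if len(signature) == 0:
        raise ValidationError("signature is empty")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    block = matrix.betas.loc[signature.probe_ids].to_numpy().T  # samples x cpgs
    if (np.ptp(block, axis=1) == 0).any():
        raise ValidationError("constant sample vector; correlation undefined")
    dist = pdist(block, metric="correlation")  # 1 - Pearson r
    z = linkage(dist, method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    sample_ids = matrix.sample_ids.tolist()
    partition = pd.Series(labels, index=sample_ids, name="cluster")
    separates: bool | None = None
    if sheet is not None:
        groups = sheet.data.loc[sample_ids, "group"]
        truth = (groups == "case").to_numpy()
        pred = labels == 1
        separates = bool((pred == truth).all() or (pred == ~truth).all())
    return ClusteringResult(
        linkage_matrix=z,
        sample_ids=sample_ids,
        partition=partition,
        separates_groups=separates,
    )


def linkage_to_newick(result: ClusteringResult) -> str:
    """Serialize the cluster tree as Newick with sample ids as leaves."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(result.linkage_matrix, result.sample_ids)
    return str(tree)


def confounder_checks(
    scores: list[ScoreResult] | None,
    sheet: SampleSheet,
    extra_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Nonparametric covariate checks; raw p-values, no correction.

    Cohort-composition tests between cases and controls: sex by chi-square,
    age by Wilcoxon rank-sum. Within controls, association of the SS score
    with sex (Wilcoxon), age (Spearman) and batch (Kruskal-Wallis); any
    ``extra_covariates`` column is tested like age if numeric, like batch
    otherwise. Covariates with a single observed level are skipped with a
    warning.
    """
    rows: list[dict] = []
    d = sheet.data
    case = d[d["group"] == "case"]
    ctrl = d[d["group"] == "control"]

    def _skip(cov: str, why: str) -> None:
        logger.warning("skipping confounder check for %r: %s", cov, why)

    if len(case) and len(ctrl):
        sexes = [s for s in ("M", "F") ]
        table = [
            [int((g["sex"] == s).sum()) for s in sexes] for g in (case, ctrl)
        ]
        if min(map(sum, table)) > 0 and all(any(col) for col in zip(*table)):
            # Pearson chi-square without Yates continuity correction: for the
            # 2x2 sex table this is the convention matching published cohort
            # demographics in this setting
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"covariate": "sex(case vs control)", "test": "chi-square", "p": p})
        else:
            _skip("sex", "a sex level is absent in one group")
        ca, co = case["age"].dropna(), ctrl["age"].dropna()
        if len(ca) and len(co):
            p = stats.mannwhitneyu(ca, co, alternative="two-sided").pvalue
            rows.append({"covariate": "age(case vs control)", "test": "wilcoxon rank-sum", "p": float(p)})

    if scores:
        sc = pd.Series({r.sample_id: r.score for r in scores})
        ctrl_ids = [s for s in sc.index if s in d.index and d.loc[s, "group"] == "control"]
        sub = d.loc[ctrl_ids]
        s_ctrl = sc.loc[ctrl_ids]
        if len(ctrl_ids) >= 3:
            m = s_ctrl[sub["sex"] == "M"]
            f = s_ctrl[sub["sex"] == "F"]
            if len(m) and len(f):
                p = stats.mannwhitneyu(m, f, alternative="two-sided").pvalue
                rows.append({"covariate": "score~sex(controls)", "test": "wilcoxon rank-sum", "p": float(p)})
            else:
                _skip("score~sex", "single sex level among controls")
            ages = pd.to_numeric(sub["age"], errors="coerce")
            ok = ages.notna()
            if ok.sum() >= 3 and ages[ok].nunique() > 1:
                rho, p = stats.spearmanr(s_ctrl[ok], ages[ok])
                rows.append({"covariate": "score~age(controls)", "test": "spearman", "p": float(p)})
            covs = [("batch", sub["batch"])]
            for name in extra_covariates or []:
                col = sub[name]
                if pd.to_numeric(col, errors="coerce").notna().all():
                    num = pd.to_numeric(col)
                    if num.nunique() > 1:
                        rho, p = stats.spearmanr(s_ctrl, num)
                        rows.append({"covariate": f"score~{name}(controls)", "test": "spearman", "p": float(p)})
                    else:
                        _skip(name, "single level")
                    continue
                covs.append((name, col))
            for name, col in covs:
                levels = col.dropna().unique()
                if len(levels) < 2:
                    _skip(f"score~{name}", "single level")
                    continue
                groups = [s_ctrl[col == lv].to_numpy() for lv in levels]
                stat, p = stats.kruskal(*groups)
                rows.append({"covariate": f"score~{name}(controls)", "test": "kruskal-wallis", "p": float(p)})
    return pd.DataFrame(rows, columns=["covariate", "test", "p"])
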