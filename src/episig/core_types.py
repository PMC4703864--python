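"""Domain types and file I/O for methylation episignature analysis.

The central objects are a beta-value matrix (CpG probes x samples, methylation
fractions in [0, 1], optionally paired with detection p-values), a sample
sheet with group labels and covariates, an Illumina-manifest-style probe
annotation table, and the pipeline configuration. All tabular I/O is plain
TSV/CSV; a minimal GEO series-matrix dialect is also read so that deposited
beta matrices can be loaded from disk without any network access.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("episig")

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "Config",
    "SignatureSet",
    "ReferenceProfiles",
    "ValidationError",
    "ParseError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_signature",
    "write_signature",
]

GROUPS = ("case", "control", "query")
SEXES = ("M", "F", "unknown")
FLOAT_FMT = "%.6f"  # array beta precision is far coarser than 6 decimals


class ValidationError(ValueError):
    """A value violates a domain invariant (range, uniqueness, shape)."""


class ParseError(ValueError):
    """A file does not conform to the expected layout."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``betas`` is a float DataFrame indexed by probe id with sample-id
    columns; NaN encodes a missing measurement. ``detection_p``, when
    present, has identical shape and axis labels.
    """

    betas: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        b = self.betas
        if b.index.has_duplicates:
            dup = b.index[b.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dup[:5]}")
        if b.columns.has_duplicates:
            dup = b.columns[b.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        vals = b.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{b.index[i]!r}, sample {b.columns[j]!r}"
            )
        if self.detection_p is not None:
            p = self.detection_p
            if p.shape != b.shape or not p.index.equals(b.index) or not p.columns.equals(b.columns):
                raise ValidationError("detection_p shape/labels differ from betas")

    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.betas.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return BetaMatrix(self.betas.loc[probe_ids], dp)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p[list(sample_ids)]
        return BetaMatrix(self.betas[list(sample_ids)], dp)


SAMPLE_SHEET_COLUMNS = ["group", "sex", "age", "batch", "family_id", "tissue"]


@dataclass
class SampleSheet:
    """Per-sample metadata: group label plus optional covariates.

    ``data`` is indexed by sample_id with columns group, sex, age, batch,
    family_id, tissue. A family_id shared by >=2 samples marks relatives;
    singleton family ids are ignored downstream.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        if "group" not in d.columns:
            raise ParseError("sample sheet lacks required column 'group'")
        bad_groups = set(d["group"].dropna()) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in d.columns:
                d[col] = np.nan
        if d["sex"].notna().any():
            bad_sex = set(d["sex"].dropna()) - set(SEXES)
            if bad_sex:
                raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        ages = pd.to_numeric(d["age"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise ValidationError("negative age")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def ids_in_group(self, group: str) -> list[str]:
        return self.data.index[self.data["group"] == group].tolist()

    @property
    def case_ids(self) -> list[str]:
        return self.ids_in_group("case")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_in_group("control")

    def case_families(self) -> dict[str, list[str]]:
        """Families with >=2 case members; singletons are dropped with a warning."""
        fams: dict[str, list[str]] = {}
        cases = self.data[self.data["group"] == "case"]
        for fid, sub in cases.groupby("family_id", dropna=True):
            members = sub.index.tolist()
            if len(members) >= 2:
                fams[str(fid)] = members
            else:
                logger.warning(
                    "case family %r has a single member; treated as non-familial", fid
                )
        return fams


ANNOTATION_COLUMNS = [
    "snp_flag_cg",
    "snp_flag_extension",
    "snp_flag_10bp",
    "snp_maf",
    "cross_reactive",
    "refgene_group",
    "island_relation",
    "enhancer",
    "dhs",
    "dmr_class",
    "regulatory_feature",
]
BOOL_ANNOTATION_COLUMNS = [
    "snp_flag_cg",
    "snp_flag_extension",
    "snp_flag_10bp",
    "cross_reactive",
    "enhancer",
    "dhs",
]


@dataclass
class ProbeAnnotation:
    """Illumina-manifest-style probe annotation, indexed by probe id.

    SNP flags mark a polymorphism at the interrogated C/G, at the
    single-base-extension position (Infinium I) or within 10 bases of the
    query site; snp_maf is the minor-allele frequency when known.
    cross_reactive marks probes aligning to multiple genomic positions at
    >=90% identity. The remaining columns are genomic-context categories.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dup[:5]}")
        for col in ANNOTATION_COLUMNS:
            if col not in d.columns:
                d[col] = False if col in BOOL_ANNOTATION_COLUMNS else np.nan
        maf = pd.to_numeric(d["snp_maf"], errors="coerce")
        known = maf.dropna()
        if ((known < 0) | (known > 1)).any():
            raise ValidationError("snp_maf outside [0, 1]")
        d["snp_maf"] = maf
        for col in BOOL_ANNOTATION_COLUMNS:
            d[col] = d[col].fillna(False).astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class Config:
    """Pipeline thresholds.

    alpha: per-trial significance level applied to Bonferroni-adjusted q.
    effect_size_min: minimum |mean_case - mean_control| on the beta scale.
    detection_p_max: probes with any detection p above this are dropped.
    maf_threshold: SNP-flagged probes with MAF >= this (or unknown MAF) are
    dropped; 0.01 is the primary cutoff, 0.05 the lenient alternative.
    score_threshold: decision boundary on the SS score (classify by sign).
    min_coverage: minimum fraction of signature CpGs a sample must cover.
    """

    alpha: float = 0.05
    effect_size_min: float = 0.20
    detection_p_max: float = 0.01
    maf_threshold: float = 0.01
    score_threshold: float = 0.0
    min_coverage: float = 0.90
    linkage_method: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 <= self.effect_size_min <= 1:
            raise ValidationError("effect_size_min must be in [0, 1]")
        if not 0 < self.detection_p_max < 1:
            raise ValidationError("detection_p_max must be in (0, 1)")
        if not 0 <= self.maf_threshold <= 1:
            raise ValidationError("maf_threshold must be in [0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValidationError("min_coverage must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**{k: v for k, v in raw.items() if k in names})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "Config":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# --- signature containers -------------------------------------------------

DIRECTIONS = ("loss", "gain")

SIGNATURE_STAT_COLUMNS = [
    "direction",
    "mean_case",
    "mean_control",
    "delta_beta",
]


@dataclass
class SignatureSet:
    """A derived episignature: member CpGs with direction and test results.

    ``stats`` is indexed by probe_id with columns direction, mean_case,
    mean_control, delta_beta (trial-averaged) and per-trial columns
    U_trial{i}, p_trial{i}, q_trial{i}, delta_trial{i}. ``m`` is the number
    of tests used for the Bonferroni correction, ``n_trials`` the number of
    family-representative trials.
    """

    stats: pd.DataFrame
    m: int
    n_trials: int

    def __post_init__(self) -> None:
        d = self.stats
        if d.index.has_duplicates:
            raise ValidationError("duplicate signature probe ids")
        if len(d):
            bad = set(d["direction"]) - set(DIRECTIONS)
            if bad:
                raise ValidationError(f"unknown direction values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stats)

    @property
    def probe_ids(self) -> pd.Index:
        return self.stats.index

    def direction_counts(self) -> dict[str, int]:
        c = self.stats["direction"].value_counts()
        return {d: int(c.get(d, 0)) for d in DIRECTIONS}

    def direction_split(self) -> dict[str, float]:
        """Percentage of signature CpGs per direction (loss/gain), 1 decimal."""
        counts = self.direction_counts()
        total = sum(counts.values())
        if total == 0:
            return {d: float("nan") for d in DIRECTIONS}
        return {d: round(100.0 * n / total, 1) for d, n in counts.items()}


@dataclass
class ReferenceProfiles:
    """Per-signature-CpG median beta for discovery cases and controls."""

    m_case: pd.Series
    m_control: pd.Series

    def __post_init__(self) -> None:
        if not self.m_case.index.equals(self.m_control.index):
            raise ValidationError("reference profiles have mismatched probe ids")
        for name, s in (("case", self.m_case), ("control", self.m_control)):
            v = s.to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ValidationError(f"{name} median profile outside [0, 1]")
            if len(v) > 1 and np.ptp(v) == 0:
                raise ValidationError(f"{name} median profile is constant")

    @property
    def probe_ids(self) -> pd.Index:
        return self.m_case.index

    def __len__(self) -> int:
        return len(self.m_case)


# --- readers / writers ----------------------------------------------------


def _read_table(path, sep) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, comment=None)
    if df.index.name is None and df.index.isna().any():
        raise ParseError(f"{path}: malformed header or index column")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_series_matrix(path) -> pd.DataFrame:
    """Minimal GEO series-matrix dialect: '!' header lines, data between
    series_matrix_table_begin/end markers."""
    lines = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            low = line.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table and line.strip():
                lines.append(line)
    if not lines:
        raise ParseError(f"{path}: no series_matrix table found")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return df


def read_beta_matrix(path, format: str = "tsv", detection_p_path=None) -> BetaMatrix:
    """Read a beta matrix (probes in rows, samples in columns).

    Blank cells become missing values; values outside [0, 1] raise a
    :class:`ValidationError` naming the offending probe and sample.
    """
    if format == "tsv":
        betas = _read_table(path, "\t")
    elif format == "csv":
        betas = _read_table(path, ",")
    elif format == "series_matrix":
        betas = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    try:
        betas = betas.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric beta value ({exc})") from exc
    dp = None
    if detection_p_path is not None:
        sep = "," if format == "csv" else "\t"
        dp = _read_table(detection_p_path, sep).astype(float)
    return BetaMatrix(betas, dp)


def write_beta_matrix(matrix: BetaMatrix, path, detection_p_path=None, sep="\t") -> None:
    matrix.betas.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="probe_id")
    if detection_p_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(
            detection_p_path, sep=sep, float_format=FLOAT_FMT, index_label="probe_id"
        )


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "batch": str, "family_id": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"sample sheet missing required column {col!r}")
    extra = set(df.columns) - {"sample_id", *SAMPLE_SHEET_COLUMNS}
    if extra:
        logger.warning("ignoring unknown sample-sheet columns: %s", sorted(extra))
        df = df.drop(columns=sorted(extra))
    df = df.set_index("sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data[SAMPLE_SHEET_COLUMNS].to_csv(path, index_label="sample_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.data.to_csv(path, sep="\t", index_label="probe_id")


SIGNATURE_FORMAT_VERSION = "1"


def write_signature(
    signature: SignatureSet,
    path,
    profiles: ReferenceProfiles | None = None,
    config: Config | None = None,
) -> None:
    """Serialize a signature as TSV with '#'-prefixed provenance records."""
    table = signature.stats.copy()
    if profiles is not None:
        if not profiles.probe_ids.equals(signature.probe_ids):
            raise ValidationError("reference profiles do not match signature probes")
        table["ref_case_median"] = profiles.m_case
        table["ref_control_median"] = profiles.m_control
    header = {
        "format_version": SIGNATURE_FORMAT_VERSION,
        "m": signature.m,
        "n_trials": signature.n_trials,
    }
    if config is not None:
        header["config"] = config.to_dict()
    with open(path, "w") as fh:
        fh.write(f"# episig-signature {json.dumps(header)}\n")
        table.to_csv(fh, sep="\t", float_format="%.10g", index_label="probe_id")


def read_signature(path) -> tuple[SignatureSet, ReferenceProfiles | None]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# episig-signature "):
            raise ParseError(f"{path}: not an episig signature file")
        try:
            header = json.loads(first[len("# episig-signature "):])
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: bad signature header") from exc
        if header.get("format_version") != SIGNATURE_FORMAT_VERSION:
            raise ParseError(
                f"{path}: unsupported signature format version "
                f"{header.get('format_version')!r}"
            )
        table = pd.read_csv(fh, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    profiles = None
    if "ref_case_median" in table.columns:
        profiles = ReferenceProfiles(
            table["ref_case_median"].rename("m_case"),
            table["ref_control_median"].rename("m_control"),
        )
        table = table.drop(columns=["ref_case_median", "ref_control_median"])
    sig = SignatureSet(table, m=int(header["m"]), n_trials=int(header["n_trials"]))
    return sig, profiles
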