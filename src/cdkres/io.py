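"""Tabular readers/writers and run configuration.

All on-disk formats are TSV with 1-based inclusive coordinates.  Every
reader validates its contract and every writer emits a deterministic
column order, so ``read(write(x)) == x`` on valid data.  Missing values
are encoded as the empty string.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .genome import GenomeModel, normalize_chrom

log = logging.getLogger(__name__)

#: consequence vocabulary for variant tables; the first six classes are the
#: protein-altering classes counted by the mutational-burden feature
TMB_CONSEQUENCES = (
    "essential_splice_site",
    "frameshift",
    "inframe_indel",
    "missense",
    "nonsense",
    "stop_loss",
)
NON_CODING_CONSEQUENCES = (
    "synonymous",
    "intronic",
    "utr_5",
    "utr_3",
    "upstream",
    "downstream",
    "intergenic",
    "splice_region",
)
CONSEQUENCES = TMB_CONSEQUENCES + NON_CODING_CONSEQUENCES

TIMEPOINTS = ("BL", "OT6", "OT12", "PD")

#: gene-level longitudinal event kinds (mutations, CNVs, fusions)
EVENT_KINDS = (
    "missense",
    "frameshift",
    "inframe_deletion",
    "nonsense",
    "splice",
    "germline",
    "amplification",
    "deletion",
    "fusion",
)
CNV_KINDS = ("amplification", "deletion")

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "cn_major", "cn_minor"]
VARIANT_COLUMNS = [
    "sample", "gene", "chrom", "pos", "ref", "alt", "consequence", "origin", "clinvar",
]
EVENT_COLUMNS = [
    "patient", "timepoint", "gene", "event_kind", "detail", "cn", "expr_quartile",
]
CLINICAL_COLUMNS = ["patient", "pfs_months", "event"]


# ---------------------------------------------------------------------------
# segments

def read_segments(path: str | Path, genome: GenomeModel) -> pd.DataFrame:
    """Read allele-specific copy-number segments (SEG-like TSV).

    Returns a frame sorted by (sample, chrom, start) with chromosome names
    normalized and coordinates clipped to chromosome length.  Overlapping
    segments within a sample/chromosome are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    df = df[SEGMENT_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in ("start", "end", "cn_major", "cn_minor"):
        df[col] = df[col].astype(int)

    for row in df.itertuples():
        if row.chrom not in genome:
            raise ValueError(f"unknown chromosome {row.chrom!r} in segment table")
        if row.end > genome[row.chrom].length:
            raise ValueError(
                f"segment {row.sample} {row.chrom}:{row.start}-{row.end} "
                f"exceeds chromosome length {genome[row.chrom].length}"
            )
        if row.start < 1 or row.start > row.end:
            raise ValueError(f"invalid interval {row.chrom}:{row.start}-{row.end}")
        if row.cn_major < row.cn_minor:
            raise ValueError(
                f"cn_major < cn_minor ({row.cn_major} < {row.cn_minor}) at "
                f"{row.sample} {row.chrom}:{row.start}-{row.end}"
            )
        if min(row.cn_major, row.cn_minor) < 0:
            raise ValueError("negative copy number")

    chrom_order = {name: i for i, name in enumerate(genome.names)}
    df = df.sort_values(
        ["sample", "chrom", "start"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
    ).reset_index(drop=True)

    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        prev = None
        for row in grp.itertuples():
            if prev is not None and row.start <= prev.end:
                raise ValueError(
                    f"overlapping segments for sample {sample} on chromosome {chrom}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} and {row.chrom}:{row.start}-{row.end}"
                )
            prev = row
    return df


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants

def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like variant table; validates consequence vocabulary."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "gene": str, "chrom": str, "clinvar": str},
        keep_default_na=False,
    )
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in VARIANT_COLUMNS]
    df = df[VARIANT_COLUMNS + extra].copy()
    df["pos"] = df["pos"].astype(int)

    bad = set(df["consequence"]) - set(CONSEQUENCES)
    if bad:
        raise ValueError(
            f"unknown consequence value(s) {sorted(bad)}; allowed: {list(CONSEQUENCES)}"
        )
    bad_origin = set(df["origin"]) - {"somatic", "germline"}
    if bad_origin:
        raise ValueError(f"origin must be somatic|germline, got {sorted(bad_origin)}")
    same = df["ref"] == df["alt"]
    if same.any():
        i = int(same.idxmax())
        raise ValueError(f"ref == alt at row {i} ({df.loc[i, 'gene']})")
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    cols = VARIANT_COLUMNS + [c for c in df.columns if c not in VARIANT_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TPM matrix (first column: gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dups}")
    neg = df.lt(0)
    if neg.any().any():
        gene = neg.any(axis=1).idxmax()
        sample = neg.loc[gene].idxmax()
        raise ValueError(f"negative TPM for gene {gene!r} in sample {sample!r}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical

def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["patient"].duplicated().any():
        raise ValueError("duplicate patient rows in clinical table")
    if (df["pfs_months"] < 0).any():
        raise ValueError("pfs_months must be >= 0")
    if not set(df["event"].astype(int)) <= {0, 1}:
        raise ValueError("event must be 0 or 1")
    df["event"] = df["event"].astype(int)
    cols = CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]
    return df[cols]


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    cols = CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# longitudinal events

def read_events(path: str | Path) -> pd.DataFrame:
    """Read per-patient longitudinal gene-level event tables."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"patient": str, "gene": str, "detail": str, "expr_quartile": str},
        keep_default_na=False,
    )
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    df = df[EVENT_COLUMNS].copy()
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoint(s) {sorted(bad_tp)}; allowed: {list(TIMEPOINTS)}")
    bad_kind = set(df["event_kind"]) - set(EVENT_KINDS)
    if bad_kind:
        raise ValueError(f"unknown event kind(s) {sorted(bad_kind)}; allowed: {list(EVENT_KINDS)}")
    df["cn"] = df["cn"].replace("", "").apply(lambda x: float(x) if x != "" else float("nan"))
    key = ["patient", "timepoint", "gene", "event_kind", "detail"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise ValueError(
            f"duplicate event rows for {tuple(dup[k] for k in key)}"
        )
    cnv = df["event_kind"].isin(CNV_KINDS)
    if cnv.any():
        missing_cn = cnv & (df["cn"].isna() | (df["expr_quartile"] == ""))
        if missing_cn.any():
            row = df[missing_cn].iloc[0]
            raise ValueError(
                f"CNV event without cn/expr_quartile: {row['patient']} {row['gene']}"
            )
        bad_q = set(df.loc[cnv, "expr_quartile"]) - {"Q1", "Q2", "Q3", "Q4"}
        if bad_q:
            raise ValueError(f"expr_quartile must be Q1..Q4, got {sorted(bad_q)}")
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    out = df[EVENT_COLUMNS].copy()
    out["cn"] = out["cn"].apply(lambda x: "" if pd.isna(x) else f"{x:g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic feature/result writers

def write_features(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample feature table with 'sample' first and the rest sorted."""
    cols = [c for c in ("sample", "patient") if c in df.columns]
    cols += sorted(c for c in df.columns if c not in cols)
    df[cols].to_csv(path, sep="\t", index=False)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Every tunable threshold in the pipeline, with its default.

    Lengths are in base pairs; copy-number gates are absolute copy numbers;
    exposure/score thresholds are fractions of per-sample mutation load.
    """

    seed: int = 0
    # segment smoothing / scar scoring
    smooth_min_len: int = 3_000_000
    merge_gap: int = 3_000_000
    loh_min_len: int = 15_000_000
    tai_min_len: int = 11_000_000
    telomere_tol: int = 0
    lst_seg_min: int = 10_000_000
    lst_gap_max: int = 3_000_000
    autosomes_only: bool = True
    # signature refitting
    weight_cutoff: float = 0.06
    improvement_tol: float = 1e-3
    min_mutations: int = 10
    cohort_score_thresh: float = 0.2
    cohort_min_samples: int = 2
    # expression features
    tpm_floor: float = 0.01
    gsea_alpha: float = 0.25
    min_set_overlap: int = 5
    pam50_min_overlap: int = 30
    # PD-specific calling
    amp_cn_min: float = 6.0
    del_cn_max: float = 1.2
    disqualify_ot12: bool = True
    # survival screen
    signature_p_thresh: float = 0.01
    n_resamples: int = 500
    train_frac: float = 0.75
    l1_ratio: float = 1.0
    # io paths (optional, CLI convenience)
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
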