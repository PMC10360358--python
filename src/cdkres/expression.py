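"""Expression-derived features: log transform, proliferative index, CYT
score, single-sample gene-set scores, and nearest-centroid intrinsic
subtyping.

The proliferative index is the geometric mean TPM of an 11-gene cell-cycle
signature; the CYT (cytolytic activity) score is the geometric mean TPM of
GZMA and PRF1.  Gene-set scores are deterministic single-sample
rank-weighted running-sum enrichment scores (ssGSEA family).  Subtype
calls are nearest-centroid by Spearman correlation over the 50-gene
intrinsic-subtype panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

log = logging.getLogger(__name__)

#: 11-gene cell-cycle signature for the proliferative index
PROLIFERATION_GENES = (
    "BIRC5", "CCNB1", "CDC20", "NUF2", "CEP55", "NDC80",
    "MKI67", "PTTG1", "RRM2", "TYMS", "UBE2C",
)

CYT_GENES = ("GZMA", "PRF1")

SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "Normal")

# the canonical 50-gene intrinsic-subtype panel, grouped by marker program
_PAM50_GROUPS: dict[str, tuple[str, ...]] = {
    "luminal": (
        "ESR1", "PGR", "FOXA1", "MLPH", "SLC39A6", "NAT1", "MAPT", "BAG1",
        "BCL2", "CXXC5", "GPR160", "BLVRA",
    ),
    "proliferation": (
        "BIRC5", "CCNB1", "CDC20", "NUF2", "CEP55", "NDC80", "MKI67", "PTTG1",
        "RRM2", "TYMS", "UBE2C", "MYBL2", "MELK", "KIF2C", "CDC6", "EXO1",
        "ORC6", "UBE2T", "ANLN", "CENPF",
    ),
    "her2_amplicon": ("ERBB2", "GRB7", "FGFR4"),
    "basal": (
        "KRT5", "KRT14", "KRT17", "FOXC1", "MIA", "SFRP1", "CDH3", "EGFR",
        "PHGDH", "ACTR3B", "MYC",
    ),
    "other": ("CCNE1", "MDM2", "MMP11", "TMEM45B"),
}

PAM50_GENES = tuple(g for genes in _PAM50_GROUPS.values() for g in genes)

# per-program log2 expression level of each subtype centroid
_GROUP_LEVELS: dict[str, dict[str, float]] = {
    "luminal":       {"Basal": 1.0, "Her2": 4.0, "LumA": 9.0, "LumB": 8.0, "Normal": 6.0},
    "proliferation": {"Basal": 9.0, "Her2": 7.0, "LumA": 3.0, "LumB": 8.0, "Normal": 2.0},
    "her2_amplicon": {"Basal": 3.0, "Her2": 10.0, "LumA": 3.0, "LumB": 4.0, "Normal": 3.0},
    "basal":         {"Basal": 9.0, "Her2": 2.0, "LumA": 1.0, "LumB": 1.5, "Normal": 5.0},
    "other":         {"Basal": 6.0, "Her2": 6.0, "LumA": 4.0, "LumB": 6.0, "Normal": 4.0},
}


def synthetic_pam50_centroids() -> pd.DataFrame:
    """Deterministic synthetic subtype centroids over the 50-gene panel.

    Log2-scale profiles built from marker-program levels (luminal genes high
    in luminal subtypes, proliferation genes high in LumB/Basal, the ERBB2
    amplicon in Her2, basal keratins in Basal), with a small per-gene offset
    so each centroid has a strict gene ranking.  These are NOT the published
    centroid values — they are a synthetic fixture with the same gene panel
    and rank structure; a user-supplied centroid TSV (genes x subtypes) can
    be used instead.
    """
    rows = {}
    i = 0
    for group, genes in _PAM50_GROUPS.items():
        for g in genes:
            rows[g] = {s: _GROUP_LEVELS[group][s] + 0.013 * i for s in SUBTYPES}
            i += 1
    return pd.DataFrame.from_dict(rows, orient="index")[list(SUBTYPES)]


def log2_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """``log2(TPM + 1)`` element-wise; negative input is an error."""
    if (matrix.values < 0).any():
        raise ValueError("TPM matrix contains negative values")
    return np.log2(matrix + 1.0)


def _geometric_mean(tpm: pd.DataFrame, floor: float) -> pd.Series:
    logs = np.log(tpm.clip(lower=floor))
    return pd.Series(np.exp(logs.mean(axis=0)), index=tpm.columns)


def proliferative_index(
    matrix: pd.DataFrame,
    gene_list: tuple[str, ...] = PROLIFERATION_GENES,
    floor: float = 0.01,
) -> pd.Series:
    """Geometric mean TPM of the cell-cycle signature genes (zeros floored)."""
    present = [g for g in gene_list if g in matrix.index]
    if not present:
        raise ValueError("none of the proliferative-index genes are in the matrix")
    if len(present) < len(gene_list):
        log.warning(
            "proliferative index using %d/%d genes (missing: %s)",
            len(present), len(gene_list), sorted(set(gene_list) - set(present)),
        )
    return _geometric_mean(matrix.loc[present], floor)


def cyt_score(matrix: pd.DataFrame, floor: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean TPM of GZMA and PRF1."""
    missing = [g for g in CYT_GENES if g not in matrix.index]
    if missing:
        raise ValueError(f"CYT score genes missing from matrix: {missing}")
    return _geometric_mean(matrix.loc[list(CYT_GENES)], floor)


# ---------------------------------------------------------------------------
# single-sample gene-set scores

def _ssgsea_one(values: pd.Series, in_set: np.ndarray, alpha: float) -> float:
    # order genes by decreasing expression; ties broken by gene name for determinism
    order = np.lexsort((values.index.to_numpy(), -values.to_numpy()))
    n = len(values)
    member = in_set[order]
    weights = (np.arange(n, 0, -1, dtype=float)) ** alpha  # rank weight, top gene largest
    w_in = np.where(member, weights, 0.0)
    denom_in = w_in.sum()
    n_out = n - member.sum()
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(np.where(member, 0.0, 1.0)) / n_out
    return float((p_in - p_out).sum() / n)


def gene_set_scores(
    log_matrix: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Rank-weighted running-sum enrichment score per (gene set, sample).

    For each sample, genes are ranked by expression; the score is the
    normalized area between the weighted cumulative in-set distribution
    (weight = descending-rank ** alpha) and the uniform out-of-set
    cumulative distribution.  Depends only on within-sample ranks, so it
    is invariant to any strictly monotone transform of one sample's values.
    """
    scores = {}
    genes = log_matrix.index
    for name, members in gene_sets.items():
        in_set = np.asarray(genes.isin(set(members)))
        overlap = int(in_set.sum())
        if overlap == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix")
        if overlap < min_overlap:
            raise ValueError(
                f"gene set {name!r} overlaps the matrix by {overlap} < {min_overlap} genes"
            )
        if overlap == len(genes):
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        scores[name] = {
            sample: _ssgsea_one(log_matrix[sample], in_set, alpha)
            for sample in log_matrix.columns
        }
    return pd.DataFrame(scores).T[log_matrix.columns]


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# nearest-centroid subtyping

def pam50_classify(
    log_matrix: pd.DataFrame,
    centroids: pd.DataFrame | None = None,
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Nearest-centroid subtype call per sample by Spearman correlation.

    Ties in the maximal correlation break by fixed label order
    (Basal, Her2, LumA, LumB, Normal).
    """
    if centroids is None:
        centroids = synthetic_pam50_centroids()
    shared = [g for g in centroids.index if g in log_matrix.index]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} of {len(centroids.index)} centroid genes present; "
            f"need >= {min_overlap}"
        )
    if len(shared) < len(centroids.index):
        log.warning("subtyping on %d/%d centroid genes", len(shared), len(centroids.index))
    sub = log_matrix.loc[shared]
    cent = centroids.loc[shared]
    rows = []
    for sample in sub.columns:
        cors = {
            lab: float(spearmanr(sub[sample].to_numpy(), cent[lab].to_numpy()).statistic)
            for lab in centroids.columns
        }
        best = max(sorted(cors), key=lambda lab: cors[lab])  # sorted -> fixed tie-break
        rows.append({"sample": sample, "subtype": best, **{f"cor_{k}": v for k, v in cors.items()}})
    return pd.DataFrame(rows)
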