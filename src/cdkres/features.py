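"""Scalar per-sample features: mutational burden, BRCA1/2 pathogenic flag,
and the immunohistochemistry H-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import TMB_CONSEQUENCES

TRUNCATING = frozenset({"nonsense", "frameshift", "essential_splice_site"})
PATHOGENIC_LABELS = frozenset({"pathogenic", "likely_pathogenic"})
BRCA_GENES = frozenset({"BRCA1", "BRCA2"})


def tmb(variants: pd.DataFrame, sample: str) -> int:
    """Tumor mutational burden: raw count of protein-altering somatic mutations.

    Qualifying consequence classes: essential splice site, frameshift,
    in-frame indel, missense, nonsense, and stop-loss.
    """
    rows = variants[(variants["sample"] == sample) & (variants["origin"] == "somatic")]
    return int(rows["consequence"].isin(TMB_CONSEQUENCES).sum())


def brca_pathogenic(variants: pd.DataFrame, sample: str) -> bool:
    """True iff the sample carries a pathogenic BRCA1/2 mutation.

    Both somatic and germline rows qualify when they truncate the reading
    frame (nonsense, frameshift, essential splice site) or carry a ClinVar
    pathogenic / likely-pathogenic annotation (case-insensitive).
    """
    rows = variants[(variants["sample"] == sample) & variants["gene"].isin(BRCA_GENES)]
    if rows.empty:
        return False
    truncating = rows["consequence"].isin(TRUNCATING)
    clinvar = rows["clinvar"].fillna("").str.lower().isin(PATHOGENIC_LABELS)
    return bool((truncating | clinvar).any())


@dataclass(frozen=True)
class NucleusCounts:
    """Nuclei per staining-intensity class for one slide region."""

    n3: int
    n2: int
    n1: int
    n0: int
    region: str = "tumor-nest"  # or "whole-viable"

    def __post_init__(self) -> None:
        if min(self.n3, self.n2, self.n1, self.n0) < 0:
            raise ValueError("nucleus counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n3 + self.n2 + self.n1 + self.n0


def h_score(counts: NucleusCounts) -> float:
    """IHC H-score: ``100 * (3*n3 + 2*n2 + n1) / total``, range [0, 300]."""
    if counts.total == 0:
        raise ValueError("H-score undefined for zero nuclei")
    return 100.0 * (3 * counts.n3 + 2 * counts.n2 + counts.n1) / counts.total


def feature_table(variants: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample variant-derived features (tmb, brca_pathogenic)."""
    if samples is None:
        samples = sorted(variants["sample"].unique())
    return pd.DataFrame(
        {
            "sample": samples,
            "tmb": [tmb(variants, s) for s in samples],
            "brca_pathogenic": [brca_pathogenic(variants, s) for s in samples],
        }
    )
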