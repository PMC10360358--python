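"""Mutational-signature catalogs and exposure refitting.

Single-base substitutions are classified into the standard 96
trinucleotide contexts (pyrimidine-strand convention): six substitution
classes {C>A, C>G, C>T, T>A, T>C, T>G} x four 5' bases x four 3' bases,
ordered substitution-major, then 5' base, then 3' base (A, C, G, T).

Per-sample exposures to a reference signature set are refit by greedy
forward selection: starting from the empty set, repeatedly add the
signature whose inclusion (with non-negative least-squares re-weighting,
weights normalized to sum 1) most reduces the squared reconstruction
error of the catalog's fraction vector; stop when the relative
improvement falls below a tolerance; finally zero out weights below a
reporting cutoff (default 0.06) and renormalize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")


def context_labels() -> list[str]:
    """The 96 context labels, e.g. ``A[C>A]A``, in canonical order."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


CONTEXT_LABELS = context_labels()
_CONTEXT_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def classify_context(ref: str, alt: str, fivep: str, threep: str) -> int:
    """Map one SNV with flanking bases to its 96-context bin index.

    Purine-reference mutations are reverse-complemented so the mutated
    base is reported on the pyrimidine strand.
    """
    ref, alt, fivep, threep = (b.upper() for b in (ref, alt, fivep, threep))
    for b in (ref, alt, fivep, threep):
        if b not in COMPLEMENT:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        fivep, threep = COMPLEMENT[threep], COMPLEMENT[fivep]
    return _CONTEXT_INDEX[f"{fivep}[{ref}>{alt}]{threep}"]


def build_catalog(variants: pd.DataFrame) -> pd.DataFrame:
    """96-context catalog per sample from a variant table with context columns.

    Requires columns ``context_5p`` and ``context_3p`` alongside ref/alt.
    Non-SNV rows (multi-base ref or alt) are skipped with a logged count.
    The catalog sum equals the number of classified SNV rows per sample.
    """
    for col in ("context_5p", "context_3p"):
        if col not in variants.columns:
            raise ValueError(f"variant table lacks required column {col!r}")
    samples = sorted(variants["sample"].unique())
    mat = pd.DataFrame(0, index=CONTEXT_LABELS, columns=samples, dtype=int)
    n_skipped = 0
    for r in variants.itertuples():
        if len(r.ref) != 1 or len(r.alt) != 1 or "-" in (r.ref, r.alt):
            n_skipped += 1
            continue
        idx = classify_context(r.ref, r.alt, r.context_5p, r.context_3p)
        mat.loc[CONTEXT_LABELS[idx], r.sample] += 1
    if n_skipped:
        log.info("build_catalog: skipped %d non-SNV rows", n_skipped)
    return mat


# ---------------------------------------------------------------------------
# reference signatures

def validate_signatures(refs: pd.DataFrame, tol: float = 1e-6) -> None:
    if (refs.values < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = refs.sum(axis=0)
    off = sums[(sums - 1).abs() > tol]
    if len(off):
        raise ValueError(f"signature columns do not sum to 1: {list(off.index)}")
    if list(refs.index) != CONTEXT_LABELS:
        raise ValueError("signature matrix rows must be the 96 canonical context labels")


def synthetic_reference_signatures(k: int = 30, seed: int = 20240117) -> pd.DataFrame:
    """A deterministic synthetic stand-in for a 30-signature reference set.

    Columns are sparse Dirichlet draws over the 96 contexts (concentration
    0.1), which gives well-separated, individually peaky profiles like real
    substitution signatures.  These are NOT the published COSMIC v2
    profiles — they are a synthetic fixture for testing and simulation; any
    externally obtained 96 x K probability table can be supplied instead
    wherever a reference matrix is accepted.
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, 0.1), size=k).T
    refs = pd.DataFrame(cols, index=CONTEXT_LABELS, columns=[f"S{i + 1}" for i in range(k)])
    validate_signatures(refs, tol=1e-9)
    return refs


def load_reference_signatures(path: str | None = None) -> pd.DataFrame:
    """Load a 96 x K signature TSV, or the synthetic default when ``path`` is None."""
    if path is None:
        return synthetic_reference_signatures()
    refs = pd.read_csv(path, sep="\t", index_col=0)
    validate_signatures(refs)
    return refs


# ---------------------------------------------------------------------------
# exposure refitting

@dataclass
class ExposureFit:
    """Per-sample refit result: normalized weights over all K signatures + SSE."""

    weights: pd.Series
    residual: float

    def nonzero(self) -> pd.Series:
        return self.weights[self.weights > 0]


def _nnls_sse(frac: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, float]:
    """NNLS weights (normalized to sum 1) and the SSE of the normalized reconstruction."""
    w, _ = nnls(cols, frac)
    total = w.sum()
    if total <= 0:
        return np.zeros(cols.shape[1]), float(np.dot(frac, frac))
    w = w / total
    resid = frac - cols @ w
    return w, float(resid @ resid)


def trinucleotide_of(label: str) -> str:
    """Pyrimidine-strand trinucleotide of a context label: ``A[C>T]G`` -> ``ACG``."""
    return label[0] + label[2] + label[6]


def fit_exposures(
    catalog: pd.Series,
    refs: pd.DataFrame,
    weight_cutoff: float = 0.06,
    improvement_tol: float = 1e-3,
    min_mutations: int = 10,
    context_weights: pd.Series | None = None,
) -> ExposureFit:
    """Refit one catalog against a reference set by greedy forward selection.

    ``context_weights`` optionally renormalizes trinucleotide-context
    frequencies (e.g. exome-to-genome): a 32-entry table mapping each
    pyrimidine-strand trinucleotide to a positive factor applied to its
    four catalog bins before the fraction vector is formed.
    """
    validate_signatures(refs)
    catalog = catalog.reindex(CONTEXT_LABELS).fillna(0).astype(float)
    if context_weights is not None:
        tris = {trinucleotide_of(lab) for lab in CONTEXT_LABELS}
        missing = tris - set(context_weights.index)
        if missing:
            raise ValueError(
                f"context_weights must cover all 32 trinucleotides; missing {sorted(missing)}"
            )
        if (context_weights <= 0).any():
            raise ValueError("context_weights must be positive")
        catalog = catalog * catalog.index.map(
            lambda lab: float(context_weights[trinucleotide_of(lab)])
        )
    total = float(catalog.sum())
    if total < min_mutations:
        raise ValueError(
            f"catalog has {total:g} mutations; at least {min_mutations} are required "
            f"for a stable refit"
        )
    if total < 50:
        log.warning("catalog has only %g mutations; exposures will be noisy", total)
    frac = catalog.to_numpy(dtype=float) / total
    names = list(refs.columns)
    cols_all = refs.to_numpy(dtype=float)

    selected: list[int] = []
    best_w = np.zeros(0)
    sse = float(frac @ frac)  # empty-model reconstruction is the zero vector
    while len(selected) < len(names):
        cands = [j for j in range(len(names)) if j not in selected]
        trials = []
        for j in cands:
            idx = selected + [j]
            w, s = _nnls_sse(frac, cols_all[:, idx])
            trials.append((s, j, w))
        s_new, j_best, w_new = min(trials, key=lambda t: (t[0], t[1]))
        if s_new >= sse or (sse - s_new) / max(sse, 1e-300) < improvement_tol:
            break
        selected.append(j_best)
        best_w, sse = w_new, s_new

    weights = pd.Series(0.0, index=names)
    for idx, w in zip(selected, best_w):
        weights.iloc[idx] = w
    # reporting cutoff: zero small weights, renormalize survivors
    weights[weights < weight_cutoff] = 0.0
    s = weights.sum()
    if s > 0:
        weights = weights / s
    recon = cols_all @ weights.to_numpy()
    resid = frac - recon if s > 0 else frac
    return ExposureFit(weights=weights, residual=float(resid @ resid))


def fit_cohort(
    catalogs: pd.DataFrame, refs: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Refit every sample (catalog columns); returns samples x (signatures + residual)."""
    rows = {}
    for sample in catalogs.columns:
        fit = fit_exposures(catalogs[sample], refs, **kwargs)
        rows[sample] = pd.concat([fit.weights, pd.Series({"residual": fit.residual})])
    return pd.DataFrame(rows).T.rename_axis("sample")


def select_cohort_signatures(
    exposures: pd.DataFrame, score_thresh: float = 0.2, min_samples: int = 2
) -> list[str]:
    """Signatures whose exposure exceeds ``score_thresh`` in strictly more
    than ``min_samples`` samples (cohort-level selection rule)."""
    sig_cols = [c for c in exposures.columns if c != "residual"]
    counts = (exposures[sig_cols] > score_thresh).sum(axis=0)
    return [s for s in sig_cols if counts[s] > min_samples]
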