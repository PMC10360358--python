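"""Calling of acquired (PD-specific) genomic alterations from paired
longitudinal event tables.

An alteration is PD-specific when it is detected in the progressive-disease
(PD) biopsy but at no earlier timepoint of the same patient.  Copy-number
events must additionally pass a functional gate: amplifications need
CN > 6 with cohort expression in the upper quartile; deletions need
CN < 1.2 with expression in the lower quartile.  Events are aggregated at
the gene level — a patient contributes at most once to a gene's
acquisition frequency.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import fisher_exact

from .io import CNV_KINDS

EARLIER_TIMEPOINTS = ("BL", "OT6", "OT12")


def _event_key(row) -> tuple:
    return (row.gene, row.event_kind, row.detail)


def passes_cnv_gate(kind: str, cn: float, expr_quartile: str,
                    amp_cn_min: float = 6.0, del_cn_max: float = 1.2) -> bool:
    """Functional-relevance gate for copy-number events."""
    if kind == "amplification":
        return cn > amp_cn_min and expr_quartile == "Q4"
    if kind == "deletion":
        return cn < del_cn_max and expr_quartile == "Q1"
    return True


def call_pd_specific(
    events: pd.DataFrame,
    amp_cn_min: float = 6.0,
    del_cn_max: float = 1.2,
    disqualify_timepoints: tuple[str, ...] = EARLIER_TIMEPOINTS,
) -> pd.DataFrame:
    """PD-specific events for a single patient's longitudinal event table.

    Events are matched across timepoints by (gene, event_kind, detail).
    A PD event is emitted iff no earlier timepoint carries the same event
    and, for CNV kinds, the CN/expression gate passes.  Detection at an
    earlier timepoint disqualifies regardless of the gate.
    """
    patients = events["patient"].unique()
    if len(patients) != 1:
        raise ValueError("call_pd_specific expects events for exactly one patient")
    pd_rows = events[events["timepoint"] == "PD"]
    if pd_rows.empty and "PD" not in set(events["timepoint"]):
        raise ValueError(f"patient {patients[0]} has no PD record")
    earlier = events[events["timepoint"].isin(disqualify_timepoints)]
    if not set(events["timepoint"]) & set(disqualify_timepoints):
        raise ValueError(f"patient {patients[0]} has no pre-PD timepoint")
    seen = {_event_key(r) for r in earlier.itertuples()}
    keep = []
    for r in pd_rows.itertuples():
        if _event_key(r) in seen:
            continue
        if r.event_kind in CNV_KINDS and not passes_cnv_gate(
            r.event_kind, r.cn, r.expr_quartile, amp_cn_min, del_cn_max
        ):
            continue
        keep.append(r.Index)
    return pd_rows.loc[keep]


def call_cohort(events: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """PD-specific calls for every patient with a PD record and an earlier timepoint."""
    out = []
    for _, grp in events.groupby("patient", sort=True):
        tps = set(grp["timepoint"])
        if "PD" not in tps or not tps & set(EARLIER_TIMEPOINTS):
            continue
        out.append(call_pd_specific(grp, **kwargs))
    if not out:
        return events.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def gene_frequencies(calls: pd.DataFrame, n_paired: int) -> pd.DataFrame:
    """Per-gene acquisition count and fraction of paired patients.

    A patient contributes at most 1 to a gene regardless of how many
    PD-specific events it has in that gene.
    """
    if n_paired <= 0:
        raise ValueError("n_paired must be positive")
    counts = (
        calls.drop_duplicates(subset=["patient", "gene"])
        .groupby("gene")
        .size()
        .sort_values(ascending=False)
    )
    df = counts.rename("n_patients").reset_index()
    df["fraction"] = df["n_patients"] / n_paired
    return df


def expression_quartiles(expr: pd.Series) -> pd.Series:
    """Cohort-wide quartile labels (Q1 lowest .. Q4 highest) for one gene.

    Computed by rank percentile across samples; the upper quartile is the
    >= 75th percentile, the lower the < 25th.
    """
    pct = expr.rank(pct=True, method="average")

    def label(p: float) -> str:
        if p >= 0.75:
            return "Q4"
        if p <= 0.25:
            return "Q1"
        return "Q2" if p <= 0.5 else "Q3"

    return pct.map(label)


def prevalence_compare(
    bl_altered: dict[str, set], pd_altered: dict[str, set],
    bl_samples: set, pd_samples: set, genes: list[str],
) -> pd.DataFrame:
    """Per-gene 2x2 altered/unaltered table at BL vs PD with Fisher exact p.

    ``bl_altered``/``pd_altered`` map gene -> set of altered samples at
    that timepoint.
    """
    rows = []
    for gene in genes:
        a_bl = len(bl_altered.get(gene, set()) & bl_samples)
        a_pd = len(pd_altered.get(gene, set()) & pd_samples)
        table = [[a_bl, len(bl_samples) - a_bl], [a_pd, len(pd_samples) - a_pd]]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "bl_altered": a_bl, "bl_total": len(bl_samples),
                "pd_altered": a_pd, "pd_total": len(pd_samples),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)
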