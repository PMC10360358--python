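"""Synthetic-cohort generators with recorded ground truth.

Each generator emits inputs with exactly the statistical structure its
downstream analysis stage assumes, plus the planted truth, so every stage
is testable by recovery:

* segment profiles with isolated, non-interacting planted LOH / TAI / LST
  events on a diploid background;
* 96-context mutation catalogs drawn from known signature mixtures;
* TPM matrices with a planted proliferative shift and optional planted
  subtype profiles;
* exponential proportional-hazards PFS with known log-hazard effects and
  calibrated uniform censoring;
* paired longitudinal event tables with planted acquired alterations.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import (
    CYT_GENES,
    PAM50_GENES,
    PROLIFERATION_GENES,
    SUBTYPES,
    synthetic_pam50_centroids,
)
from .genome import MB, GenomeModel
from .io import SEGMENT_COLUMNS
from .pd_calls import passes_cnv_gate
from .signatures import CONTEXT_LABELS

# spacing constants for planted scar events (bp): background flank that keeps
# events isolated, and a gap wide enough that no transition is counted across it
_BG_FLANK = 10 * MB
_EVENT_GAP = 5 * MB


@dataclass(frozen=True)
class ScarTruth:
    loh: int
    tai: int
    lst: int


# ---------------------------------------------------------------------------
# segments

def _arms(genome: GenomeModel) -> list[tuple[str, int, int, bool]]:
    out = []
    for c in genome.autosomes():
        out.append((c.name, 1, c.cen_start - 1, True))
        out.append((c.name, c.cen_end + 1, c.length, False))
    return out


def _feasible(kind: str, arm_len: int) -> bool:
    if kind == "tai":
        return arm_len >= 11 * MB + _EVENT_GAP + _BG_FLANK
    if kind == "loh":
        return arm_len >= 16 * MB + 2 * (_EVENT_GAP + _BG_FLANK)
    if kind == "lst":
        return arm_len >= 24 * MB + 2 * (_EVENT_GAP + _BG_FLANK)
    raise ValueError(kind)


def simulate_segments(
    genome: GenomeModel,
    n_loh: int,
    n_tai: int,
    n_lst: int,
    seed: int,
    sample: str = "S1",
) -> tuple[pd.DataFrame, ScarTruth]:
    """Plant isolated scar events on a diploid background, one per arm.

    Planted LOH events are interstitial (1,0) regions of length uniform in
    [16, 40] Mb; TAI events are telomere-anchored (2,1) regions of at least
    11 Mb confined to one arm; LST events are single (1,1)|(2,1)
    change-points with both segments >= 12 Mb.  Every event is flanked by
    >= 10 Mb of diploid background with a 5 Mb coverage gap on each side,
    so events do not interact and each contributes exactly 1 to its score.
    """
    rng = np.random.default_rng(seed)
    arms = _arms(genome)
    order = rng.permutation(len(arms))
    arms = [arms[i] for i in order]

    events = ["tai"] * n_tai + ["loh"] * n_loh + ["lst"] * n_lst
    placements: dict[int, str] = {}
    free = list(range(len(arms)))
    for kind in events:
        chosen = None
        for idx in free:
            _, a0, a1, _ = arms[idx]
            if _feasible(kind, a1 - a0 + 1):
                chosen = idx
                break
        if chosen is None:
            cap = {
                k: sum(_feasible(k, a1 - a0 + 1) for _, a0, a1, _ in arms)
                for k in ("loh", "tai", "lst")
            }
            raise ValueError(
                f"cannot place {n_loh} LOH + {n_tai} TAI + {n_lst} LST events: "
                f"genome has capacity for at most {cap['loh']} LOH, {cap['tai']} TAI, "
                f"{cap['lst']} LST (one event per arm)"
            )
        placements[chosen] = kind
        free.remove(chosen)

    rows: list[tuple] = []

    def add(chrom: str, start: int, end: int, cn_major: int, cn_minor: int) -> None:
        rows.append((sample, chrom, int(start), int(end), cn_major, cn_minor))

    for idx, (chrom, a0, a1, is_p) in enumerate(arms):
        kind = placements.get(idx)
        arm_len = a1 - a0 + 1
        if kind is None:
            add(chrom, a0, a1, 1, 1)
        elif kind == "tai":
            lmax = min(40 * MB, arm_len - _EVENT_GAP - _BG_FLANK)
            L = int(rng.integers(11 * MB, lmax + 1))
            if is_p:  # anchored at the p telomere
                add(chrom, a0, a0 + L - 1, 2, 1)
                add(chrom, a0 + L + _EVENT_GAP, a1, 1, 1)
            else:  # anchored at the q telomere
                add(chrom, a0, a1 - L - _EVENT_GAP, 1, 1)
                add(chrom, a1 - L + 1, a1, 2, 1)
        elif kind == "loh":
            lmax = min(40 * MB, arm_len - 2 * (_EVENT_GAP + _BG_FLANK))
            L = int(rng.integers(16 * MB, lmax + 1))
            s = a0 + _BG_FLANK + _EVENT_GAP
            add(chrom, a0, s - _EVENT_GAP - 1, 1, 1)
            add(chrom, s, s + L - 1, 1, 0)
            add(chrom, s + L + _EVENT_GAP, a1, 1, 1)
        elif kind == "lst":
            half = (arm_len - 2 * (_EVENT_GAP + _BG_FLANK)) // 2
            lmax = min(20 * MB, half)
            L1 = int(rng.integers(12 * MB, lmax + 1))
            L2 = int(rng.integers(12 * MB, lmax + 1))
            s = a0 + _BG_FLANK + _EVENT_GAP
            add(chrom, a0, s - _EVENT_GAP - 1, 1, 1)
            add(chrom, s, s + L1 - 1, 1, 1)
            add(chrom, s + L1, s + L1 + L2 - 1, 2, 1)
            add(chrom, s + L1 + L2 + _EVENT_GAP, a1, 1, 1)

    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    chrom_order = {name: i for i, name in enumerate(genome.names)}
    df = df.sort_values(
        ["sample", "chrom", "start"],
        key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return df, ScarTruth(loh=n_loh, tai=n_tai, lst=n_lst)


# ---------------------------------------------------------------------------
# mutations

def simulate_mutations(
    exposures: pd.Series, n_mut: int, signature_matrix: pd.DataFrame, seed: int
) -> pd.Series:
    """Draw a 96-context catalog from the mixture sum_k exposure_k * signature_k."""
    if n_mut < 1:
        raise ValueError("n_mut must be >= 1")
    if (exposures < 0).any():
        raise ValueError("exposures must be non-negative")
    if abs(float(exposures.sum()) - 1.0) > 1e-9:
        raise ValueError(f"exposures must sum to 1 (got {exposures.sum()!r})")
    missing = set(exposures.index) - set(signature_matrix.columns)
    if missing:
        raise ValueError(f"exposures reference unknown signatures: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    p = signature_matrix[list(exposures.index)].to_numpy() @ exposures.to_numpy()
    p = p / p.sum()
    counts = rng.multinomial(n_mut, p)
    return pd.Series(counts, index=CONTEXT_LABELS, name="count")


def catalog_to_variants(catalog: pd.Series, sample: str = "S1") -> pd.DataFrame:
    """Expand a catalog into per-variant rows with context columns."""
    rows = []
    pos = 0
    for label, n in catalog.items():
        fivep, rest = label[0], label[2:]
        ref, alt, threep = rest[0], rest[2], rest[4]
        for _ in range(int(n)):
            pos += 1000
            rows.append(
                {
                    "sample": sample, "gene": f"G{pos}", "chrom": "1", "pos": pos,
                    "ref": ref, "alt": alt, "consequence": "missense",
                    "origin": "somatic", "clinvar": "",
                    "context_5p": fivep, "context_3p": threep,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionTruth:
    groups: pd.Series          # 0/1 proliferation group per sample
    subtypes: pd.Series | None


def simulate_expression(
    n_samples: int,
    effect: float = 1.0,
    seed: int = 0,
    n_genes: int = 600,
    subtypes: list[str] | None = None,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Log-normal TPM matrix with a planted proliferative shift.

    Half the samples (the "high" group) have the 11 proliferative-index
    genes shifted up by ``effect`` log2 units.  When ``subtypes`` is given
    (one label per sample), the 50-gene subtype panel follows the synthetic
    centroid profile of that label plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    filler = [f"GENE{i:04d}" for i in range(n_genes)]
    genes = list(dict.fromkeys(list(PAM50_GENES) + list(PROLIFERATION_GENES)
                               + list(CYT_GENES) + filler))
    samples = [f"SAMP{i:03d}" for i in range(n_samples)]
    groups = pd.Series((np.arange(n_samples) % 2), index=samples, name="prolif_group")

    mu = pd.Series(rng.normal(3.0, 1.0, size=len(genes)), index=genes)
    logx = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(len(genes), n_samples)), index=genes, columns=samples
    ).add(mu, axis=0)

    if subtypes is not None:
        if len(subtypes) != n_samples:
            raise ValueError("subtypes must have one label per sample")
        bad = set(subtypes) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        cent = synthetic_pam50_centroids()
        for j, (sample, lab) in enumerate(zip(samples, subtypes)):
            logx.loc[cent.index, sample] = (
                cent[lab].to_numpy() + rng.normal(0.0, noise_sd, size=len(cent))
            )
    for g in PROLIFERATION_GENES:
        logx.loc[g, groups == 1] += effect

    tpm = 2.0 ** logx
    truth = ExpressionTruth(
        groups=groups,
        subtypes=pd.Series(subtypes, index=samples, name="subtype") if subtypes else None,
    )
    return tpm, truth


# ---------------------------------------------------------------------------
# survival

def _calibrate_uniform_censoring(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound c of U(0, c) censoring achieving the target censor fraction.

    For censoring C ~ U(0, c) independent of T ~ Exp(h),
    P(C < T) = (1 - exp(-h c)) / (h c); the expectation over samples is
    monotone decreasing in c, so the target rate has a unique root.
    """
    def mean_censor_prob(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    return brentq(lambda c: mean_censor_prob(c) - censor_rate, 1e-9, 1e9, xtol=1e-9)


def simulate_survival(
    features: pd.DataFrame,
    beta: dict[str, float],
    censor_rate: float = 0.0,
    baseline_hazard: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards PFS: h_i = h0 * exp(x_i' beta).

    Under this model the true hazard ratio of a unit covariate change is
    exactly exp(beta).  Censoring times are uniform on (0, c) with c
    calibrated so the expected censored fraction equals ``censor_rate``.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    missing = set(beta) - set(features.columns)
    if missing:
        raise ValueError(f"beta references unknown features: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lin = np.zeros(len(features))
    for col, b in beta.items():
        lin += b * features[col].astype(float).to_numpy()
    h = baseline_hazard * np.exp(lin)
    t = rng.exponential(1.0 / h)
    if censor_rate == 0:
        pfs, event = t, np.ones(len(t), dtype=int)
    else:
        c = _calibrate_uniform_censoring(h, censor_rate)
        cens = rng.uniform(0.0, c, size=len(t))
        pfs = np.minimum(t, cens)
        event = (t <= cens).astype(int)
    out = pd.DataFrame(
        {"patient": features.index.astype(str), "pfs_months": pfs, "event": event}
    )
    return pd.concat([out.reset_index(drop=True), features.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# longitudinal events

@dataclass
class PlantedEvent:
    gene: str
    kind: str
    n_patients: int
    detail: str = ""
    cn: float = float("nan")
    expr_quartile: str = ""
    patients: list[str] = field(default_factory=list)  # filled by the generator

    @property
    def should_be_called(self) -> bool:
        """Whether the PD-specific caller ought to emit this event."""
        if self.kind in ("amplification", "deletion"):
            return passes_cnv_gate(self.kind, self.cn, self.expr_quartile)
        return True


_BASELINE_POOL = (
    ("PIK3CA", "missense", "p.H1047R"),
    ("TP53", "missense", "p.R175H"),
    ("GATA3", "frameshift", "p.P409fs"),
    ("CDH1", "nonsense", "p.Q23*"),
    ("MAP3K1", "splice", "c.1432+1G>A"),
)


def simulate_longitudinal(
    n_patients: int,
    planted_pd_events: list[PlantedEvent],
    seed: int = 0,
) -> tuple[pd.DataFrame, list[PlantedEvent]]:
    """Paired BL/OT6/PD event tables with planted acquired alterations.

    Every patient receives 1-3 baseline events (copied to OT6 and PD,
    i.e. persistent clonal alterations); planted acquired events appear
    only at PD, in a random subset of patients of the requested size.
    Default details are filled for mutation kinds; CNV kinds default to a
    gate-passing (cn, quartile) unless the planted event specifies them.
    """
    rng = np.random.default_rng(seed)
    patients = [f"PT{i:03d}" for i in range(n_patients)]
    rows = []
    for pt in patients:
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(_BASELINE_POOL), size=k, replace=False)
        for i in picks:
            gene, kind, detail = _BASELINE_POOL[i]
            for tp in ("BL", "OT6", "PD"):
                rows.append(
                    {
                        "patient": pt, "timepoint": tp, "gene": gene,
                        "event_kind": kind, "detail": detail,
                        "cn": float("nan"), "expr_quartile": "",
                    }
                )
    for ev in planted_pd_events:
        if ev.n_patients > n_patients:
            raise ValueError(
                f"planted event in {ev.gene} asks for {ev.n_patients} of {n_patients} patients"
            )
        if ev.kind in ("amplification", "deletion"):
            if np.isnan(ev.cn):
                ev.cn = 7.5 if ev.kind == "amplification" else 0.8
            if not ev.expr_quartile:
                ev.expr_quartile = "Q4" if ev.kind == "amplification" else "Q1"
        elif not ev.detail:
            ev.detail = f"p.{ev.gene[:1]}{int(rng.integers(50, 900))}X"
        chosen = rng.choice(n_patients, size=ev.n_patients, replace=False)
        ev.patients = [patients[i] for i in sorted(chosen)]
        for pt in ev.patients:
            rows.append(
                {
                    "patient": pt, "timepoint": "PD", "gene": ev.gene,
                    "event_kind": ev.kind, "detail": ev.detail,
                    "cn": ev.cn, "expr_quartile": ev.expr_quartile,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["patient", "timepoint", "gene", "event_kind", "detail", "cn", "expr_quartile"],
    ).sort_values(["patient", "timepoint", "gene", "event_kind", "detail"]).reset_index(drop=True)
    return df, planted_pd_events
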