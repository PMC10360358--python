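"""Genomic scar scores from allele-specific copy-number segments.

Three copy-number "scar" counts quantify the footprint of homologous
recombination deficiency (HRD):

* HRD-LOH — interstitial loss-of-heterozygosity regions longer than 15 Mb
  that do not span a whole chromosome;
* TAI — allelic-imbalance regions anchored at a chromosome end that do not
  cross the centromere and exceed a minimum length (default 11 Mb);
* LST — change-points between adjacent large (>= 10 Mb) segments after
  small-segment smoothing, counted per chromosome arm.

The HRD index is the unweighted sum of the three.  A CIN fraction
(fraction of covered autosomal length off the modal total copy number) is
computed alongside.  All counters operate on smoothed segments; profiles
are smoothed with a 3 Mb filter before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .genome import GenomeModel, MB


class Seg(NamedTuple):
    """One allele-specific segment on a single chromosome (1-based inclusive)."""

    start: int
    end: int
    cn_major: int
    cn_minor: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def cn(self) -> tuple[int, int]:
        return (self.cn_major, self.cn_minor)


@dataclass(frozen=True)
class ScarScores:
    loh: int
    tai: int
    lst: int

    def __post_init__(self) -> None:
        if min(self.loh, self.tai, self.lst) < 0:
            raise ValueError("scar counts must be non-negative")

    @property
    def hrd_index(self) -> int:
        return hrd_index(self.loh, self.tai, self.lst)


def hrd_index(loh: int, tai: int, lst: int) -> int:
    """Unweighted sum of the three scar counts."""
    if min(loh, tai, lst) < 0:
        raise ValueError("scar counts must be non-negative")
    return loh + tai + lst


# ---------------------------------------------------------------------------
# smoothing

def smooth_segments(
    segs: list[Seg], min_len: int = 3 * MB, merge_gap: int = 3 * MB
) -> list[Seg]:
    """Merge equal-CN neighbours and iteratively drop sub-``min_len`` segments.

    Removing a short segment merges its flanks when their allelic copy
    numbers agree, spanning the removed material.  Equal-CN neighbours
    separated by less than ``merge_gap`` are merged (spanning the gap);
    larger gaps are treated as genuinely disjoint territory.  Idempotent.
    """
    segs = sorted(segs, key=lambda s: s.start)

    def merge_pass(xs: list[Seg]) -> list[Seg]:
        out: list[Seg] = []
        for s in xs:
            if out and out[-1].cn == s.cn and s.start - out[-1].end - 1 < merge_gap:
                out[-1] = Seg(out[-1].start, max(out[-1].end, s.end), *s.cn)
            else:
                out.append(s)
        return out

    segs = merge_pass(segs)
    while True:
        short = [s for s in segs if s.length < min_len]
        if not short:
            return segs
        victim = min(short, key=lambda s: (s.length, s.start))
        i = segs.index(victim)
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i + 1 < len(segs) else None
        segs = segs[:i] + segs[i + 1 :]
        if left is not None and right is not None and left.cn == right.cn:
            # merge across the removed gap regardless of its size
            j = segs.index(left)
            segs[j] = Seg(left.start, right.end, *left.cn)
            segs.pop(j + 1)
        segs = merge_pass(segs)


# ---------------------------------------------------------------------------
# maximal-region construction (strict coordinate adjacency)

def _maximal_runs(segs: list[Seg], predicate) -> list[tuple[int, int]]:
    """Maximal (start, end) runs of strictly adjacent segments satisfying ``predicate``."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end: int | None = None
    for s in segs:
        if predicate(s):
            if cur is not None and prev_end is not None and s.start == prev_end + 1:
                cur = (cur[0], s.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (s.start, s.end)
            prev_end = s.end
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
            prev_end = s.end
    if cur is not None:
        runs.append(cur)
    return runs


# ---------------------------------------------------------------------------
# counters (single chromosome lists in, counts out)

def count_hrd_loh(
    segs_by_chrom: dict[str, list[Seg]],
    genome: GenomeModel,
    min_len: int = 15 * MB,
) -> int:
    """Count interstitial LOH regions longer than ``min_len``.

    A region is a maximal run of adjacent segments with ``cn_minor == 0``
    and ``cn_major >= 1`` (homozygous deletions do not qualify: LOH means
    one allele is retained).  Regions spanning the entire chromosome are
    excluded.
    """
    n = 0
    for chrom, segs in segs_by_chrom.items():
        c = genome[chrom]
        for start, end in _maximal_runs(segs, lambda s: s.cn_minor == 0 and s.cn_major >= 1):
            if end - start + 1 > min_len and not (start <= 1 and end >= c.length):
                n += 1
    return n


def count_tai(
    segs_by_chrom: dict[str, list[Seg]],
    genome: GenomeModel,
    min_len: int = 11 * MB,
    telomere_tol: int = 0,
) -> int:
    """Count telomere-anchored allelic-imbalance regions.

    A maximal run of adjacent imbalanced segments (``cn_major != cn_minor``)
    counts when it (a) reaches a chromosome end within ``telomere_tol`` bp,
    (b) does not cross the centromere (extend strictly beyond both of its
    boundaries), and (c) is at least ``min_len`` long.
    """
    n = 0
    for chrom, segs in segs_by_chrom.items():
        c = genome[chrom]
        for start, end in _maximal_runs(segs, lambda s: s.cn_major != s.cn_minor):
            reaches_telomere = start <= 1 + telomere_tol or end >= c.length - telomere_tol
            crosses_cen = start < c.cen_start and end > c.cen_end
            if reaches_telomere and not crosses_cen and end - start + 1 >= min_len:
                n += 1
    return n


def split_at_arm_boundary(segs: list[Seg], boundary: int) -> tuple[list[Seg], list[Seg]]:
    """Split a chromosome's segments into p-arm/q-arm lists at ``boundary``.

    A segment straddling the boundary contributes a piece to each arm.
    """
    p, q = [], []
    for s in segs:
        if s.end <= boundary:
            p.append(s)
        elif s.start > boundary:
            q.append(s)
        else:
            p.append(Seg(s.start, boundary, *s.cn))
            q.append(Seg(boundary + 1, s.end, *s.cn))
    return p, q


def count_lst(
    segs_by_chrom: dict[str, list[Seg]],
    genome: GenomeModel,
    seg_min: int = 10 * MB,
    gap_max: int = 3 * MB,
) -> int:
    """Count large-scale transitions per chromosome arm.

    On each arm (split at the centromere midpoint), a transition is an
    ordered pair of consecutive segments with different allelic copy
    number, each at least ``seg_min`` long, separated by less than
    ``gap_max``.  Input must already be smoothed at 3 Mb.
    """
    n = 0
    for chrom, segs in segs_by_chrom.items():
        c = genome[chrom]
        for arm in split_at_arm_boundary(segs, c.cen_mid):
            for a, b in zip(arm, arm[1:]):
                gap = b.start - a.end - 1
                if a.cn != b.cn and a.length >= seg_min and b.length >= seg_min and gap < gap_max:
                    n += 1
    return n


def compute_cin(segs_by_chrom: dict[str, list[Seg]]) -> float:
    """Fraction of covered length whose total CN differs from the modal total CN.

    The mode is length-weighted; ties break toward the smaller total CN.
    """
    lengths: dict[int, int] = {}
    total = 0
    for segs in segs_by_chrom.values():
        for s in segs:
            tcn = s.cn_major + s.cn_minor
            lengths[tcn] = lengths.get(tcn, 0) + s.length
            total += s.length
    if total == 0:
        raise ValueError("cannot compute CIN on an empty segment set")
    modal = max(sorted(lengths), key=lambda k: lengths[k])
    return 1.0 - lengths[modal] / total


# ---------------------------------------------------------------------------
# sample / cohort entry points

def _sample_segments(df: pd.DataFrame, genome: GenomeModel, autosomes_only: bool) -> dict[str, list[Seg]]:
    out: dict[str, list[Seg]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        if autosomes_only and not genome[chrom].is_autosome:
            continue
        out[chrom] = [
            Seg(int(r.start), int(r.end), int(r.cn_major), int(r.cn_minor))
            for r in grp.sort_values("start").itertuples()
        ]
    return out


def score_sample(
    df: pd.DataFrame,
    genome: GenomeModel,
    *,
    smooth_min_len: int = 3 * MB,
    merge_gap: int = 3 * MB,
    loh_min_len: int = 15 * MB,
    tai_min_len: int = 11 * MB,
    telomere_tol: int = 0,
    lst_seg_min: int = 10 * MB,
    lst_gap_max: int = 3 * MB,
    autosomes_only: bool = True,
) -> dict:
    """Scar scores + CIN for one sample's segment frame."""
    raw = _sample_segments(df, genome, autosomes_only)
    smoothed = {
        chrom: smooth_segments(segs, min_len=smooth_min_len, merge_gap=merge_gap)
        for chrom, segs in raw.items()
    }
    loh = count_hrd_loh(smoothed, genome, min_len=loh_min_len)
    tai = count_tai(smoothed, genome, min_len=tai_min_len, telomere_tol=telomere_tol)
    lst = count_lst(smoothed, genome, seg_min=lst_seg_min, gap_max=lst_gap_max)
    return {
        "loh": loh,
        "tai": tai,
        "lst": lst,
        "hrd_index": hrd_index(loh, tai, lst),
        "cin": compute_cin(smoothed),
    }


def score_cohort(segments: pd.DataFrame, genome: GenomeModel, **kwargs) -> pd.DataFrame:
    """Per-sample scar table (columns sample, loh, tai, lst, hrd_index, cin)."""
    rows = []
    for sample, grp in segments.groupby("sample", sort=True):
        rows.append({"sample": sample, **score_sample(grp, genome, **kwargs)})
    return pd.DataFrame(rows, columns=["sample", "loh", "tai", "lst", "hrd_index", "cin"])
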