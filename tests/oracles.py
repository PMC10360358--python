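"""Independent brute-force oracles used by the test suite.

Each oracle re-states the counting rule directly (enumerate every
candidate region, test it against the written rule) without sharing code
with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import nnls
from scipy.stats import chi2


def enumerate_maximal_runs(segs, pred):
    """All maximal runs [i..j] of strictly adjacent segments satisfying pred.

    ``segs`` is a list of (start, end, cn_major, cn_minor) tuples sorted by
    start.  Returns (start, end) spans.
    """
    n = len(segs)
    ok = [pred(s) for s in segs]
    adjacent = [
        segs[i + 1][0] == segs[i][1] + 1 for i in range(n - 1)
    ]
    runs = []
    for i in range(n):
        for j in range(i, n):
            if not all(ok[i : j + 1]):
                continue
            if not all(adjacent[i:j]):
                continue
            left_ext = i > 0 and ok[i - 1] and adjacent[i - 1]
            right_ext = j < n - 1 and ok[j + 1] and adjacent[j]
            if left_ext or right_ext:
                continue  # not maximal
            runs.append((segs[i][0], segs[j][1]))
    return runs


def brute_hrd_loh(segs_by_chrom, genome, min_len=15_000_000):
    count = 0
    for chrom, segs in segs_by_chrom.items():
        c = genome[chrom]
        runs = enumerate_maximal_runs(segs, lambda s: s[3] == 0 and s[2] >= 1)
        for start, end in runs:
            length = end - start + 1
            whole = start <= 1 and end >= c.length
            if length > min_len and not whole:
                count += 1
    return count


def brute_tai(segs_by_chrom, genome, min_len=11_000_000, telomere_tol=0):
    count = 0
    for chrom, segs in segs_by_chrom.items():
        c = genome[chrom]
        runs = enumerate_maximal_runs(segs, lambda s: s[2] != s[3])
        for start, end in runs:
            at_telomere = start <= 1 + telomere_tol or end >= c.length - telomere_tol
            crosses = start < c.cen_start and end > c.cen_end
            if at_telomere and not crosses and end - start + 1 >= min_len:
                count += 1
    return count


def brute_lst(segs_by_chrom, genome, seg_min=10_000_000, gap_max=3_000_000):
    count = 0
    for chrom, segs in segs_by_chrom.items():
        boundary = (genome[chrom].cen_start + genome[chrom].cen_end) // 2
        arms = {"p": [], "q": []}
        for start, end, a, b in segs:
            if end <= boundary:
                arms["p"].append((start, end, a, b))
            elif start > boundary:
                arms["q"].append((start, end, a, b))
            else:
                arms["p"].append((start, boundary, a, b))
                arms["q"].append((boundary + 1, end, a, b))
        for arm in arms.values():
            for (s1, e1, a1, b1), (s2, e2, a2, b2) in zip(arm, arm[1:]):
                if (a1, b1) == (a2, b2):
                    continue
                if e1 - s1 + 1 < seg_min or e2 - s2 + 1 < seg_min:
                    continue
                if s2 - e1 - 1 < gap_max:
                    count += 1
    return count


def brute_cin(segs_by_chrom):
    by_cn = {}
    total = 0
    for segs in segs_by_chrom.values():
        for start, end, a, b in segs:
            by_cn[a + b] = by_cn.get(a + b, 0) + (end - start + 1)
            total += end - start + 1
    modal = max(sorted(by_cn), key=lambda k: by_cn[k])
    return 1.0 - by_cn[modal] / total


def random_profile(rng, genome, max_segments=40):
    """Random small segment profile for oracle-equivalence testing."""
    cn_pool = [(1, 1), (1, 1), (2, 1), (1, 0), (2, 2), (3, 1), (2, 0), (0, 0), (4, 2)]
    segs_by_chrom = {}
    n_total = 0
    for c in genome.autosomes():
        if n_total >= max_segments:
            break
        pos = 1
        segs = []
        n_here = int(rng.integers(1, 7))
        for _ in range(n_here):
            if n_total >= max_segments or pos >= c.length:
                break
            length = int(rng.integers(1, 31)) * 1_000_000 + int(rng.integers(0, 1000))
            end = min(pos + length - 1, c.length)
            a, b = cn_pool[int(rng.integers(len(cn_pool)))]
            segs.append((pos, end, a, b))
            n_total += 1
            gap = int(rng.integers(0, 7)) * 1_000_000
            pos = end + 1 + gap
        if segs:
            segs_by_chrom[c.name] = segs
    return segs_by_chrom


# ---------------------------------------------------------------------------
# signature refitting

def nnls_normalized_sse(frac, cols):
    w, _ = nnls(cols, frac)
    if w.sum() <= 0:
        return np.zeros(cols.shape[1]), float(frac @ frac)
    w = w / w.sum()
    r = frac - cols @ w
    return w, float(r @ r)


def exhaustive_best_subset(frac, refs):
    """Best normalized-NNLS SSE over all non-empty signature subsets."""
    names = list(refs.columns)
    cols = refs.to_numpy(float)
    best = (float("inf"), ())
    for r in range(1, len(names) + 1):
        for subset in combinations(range(len(names)), r):
            _, sse = nnls_normalized_sse(frac, cols[:, list(subset)])
            if sse < best[0] - 1e-15:
                best = (sse, tuple(names[i] for i in subset))
    return best


# ---------------------------------------------------------------------------
# survival

def hand_logrank_p(times1, events1, times0, events0):
    """Two-group log-rank test from the observed-minus-expected tables."""
    data = [(t, e, 1) for t, e in zip(times1, events1)] + [
        (t, e, 0) for t, e in zip(times0, events0)
    ]
    event_times = sorted({t for t, e, _ in data if e == 1})
    O = E = V = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 1)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (O - E) ** 2 / V
    return float(chi2.sf(stat, df=1))


def hand_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * n / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)
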