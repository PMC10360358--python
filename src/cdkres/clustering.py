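"""Two-group stratification of samples from feature matrices.

Ward hierarchical clustering on z-scored features, cut at k=2, with
cluster names assigned by feature semantics rather than tree order: the
cluster with the higher mean of a designated anchor feature gets the
"high" label (e.g. higher mean HRD index -> HRD-H; higher mean
proliferative index -> PC2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

#: default feature panel for the HRD-high/low stratification
HRD_CLUSTER_FEATURES = ("loh", "tai", "lst", "hrd_index", "S3", "S2", "S13", "tmb", "cin")


@dataclass
class ClusterAssignment:
    labels: pd.Series            # sample -> semantic label
    linkage_matrix: np.ndarray
    newick: str


def select_prognostic_signatures(
    screen: pd.DataFrame, p_thresh: float = 0.01, p_col: str = "logrank_p"
) -> list[str]:
    """Features from a survival screen with p strictly below ``p_thresh``."""
    return screen.loc[screen[p_col] < p_thresh, "feature"].tolist()


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    tree = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return f"({rec(tree.left)},{rec(tree.right)});"


def cluster_two(
    features: pd.DataFrame,
    anchor: str,
    high_label: str,
    low_label: str,
) -> ClusterAssignment:
    """Ward/Euclidean clustering of samples (rows) cut at two groups.

    ``anchor`` names the feature whose cluster-mean decides which group
    gets ``high_label``.  Features are z-scored column-wise; a matrix with
    no variation anywhere is an error.
    """
    if len(features) < 4:
        raise ValueError("need at least 4 samples to cluster")
    if anchor not in features.columns:
        raise ValueError(f"anchor feature {anchor!r} not in matrix")
    X = features.astype(float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("constant feature matrix: nothing to cluster")
    keep = sd[sd > 0].index
    Z = ((X[keep] - X[keep].mean(axis=0)) / sd[keep]).to_numpy()
    # sort samples so the assignment is invariant to input row order
    order = np.argsort(features.index.to_numpy())
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    names = [str(s) for s in features.index[order]]
    L = linkage(Z[order], method="ward", metric="euclidean")
    flat = fcluster(L, t=2, criterion="maxclust")[inv]

    means = {c: features.loc[flat == c, anchor].mean() for c in (1, 2)}
    high_cluster = max(sorted(means), key=lambda c: means[c])
    labels = pd.Series(
        [high_label if c == high_cluster else low_label for c in flat],
        index=features.index,
        name="cluster",
    )
    return ClusterAssignment(
        labels=labels, linkage_matrix=L, newick=_linkage_to_newick(L, names)
    )
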