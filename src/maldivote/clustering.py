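"""Agglomerative hierarchical clustering of samples on selected signals.

Defaults follow the Eisen Cluster conventions: distance = 1 - uncentered
correlation and average linkage, both configurable (centered Pearson,
Euclidean; complete linkage).  A deterministic dendrogram is produced by
canonically ordering each merge's children (subtree containing the
lexicographically smallest sample id first), and the two-branch cut
summarizes per-branch class composition with exact binomial CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DataError
from .evaluation import clopper_pearson, round_percent
from .preprocessing import FeatureTable

__all__ = ["Dendrogram", "hierarchical_cluster", "branch_purity",
           "pairwise_distance"]


def pairwise_distance(X: np.ndarray, sample_ids: list[str],
                      metric: str = "uncentered") -> np.ndarray:
    """Square distance matrix between sample rows.

    ``uncentered``: 1 - (x.y)/(|x||y|) (Eisen's uncentered correlation);
    ``pearson``: 1 - centered correlation; ``euclidean``: L2 distance.
    Degenerate rows (zero norm / zero variance under the correlation
    metrics) raise, naming the sample.
    """
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return squareform(pdist(X))
    if metric == "uncentered":
        norms = np.sqrt((X**2).sum(axis=1))
        bad = [sample_ids[i] for i in np.where(norms == 0)[0]]
        if bad:
            raise DataError(f"all-zero sample(s) under uncentered correlation: {bad}")
        sim = (X @ X.T) / np.outer(norms, norms)
    elif metric == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((Xc**2).sum(axis=1))
        bad = [sample_ids[i] for i in np.where(norms == 0)[0]]
        if bad:
            raise DataError(f"constant sample(s) under Pearson correlation: {bad}")
        sim = (Xc @ Xc.T) / np.outer(norms, norms)
    else:
        raise ConfigurationError(f"unknown metric: {metric!r}")
    return 1.0 - np.clip(sim, -1.0, 1.0)


@dataclass
class Dendrogram:
    """Merge tree over samples with heights and a canonical leaf order."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    sample_ids: list[str]
    metric: str
    linkage: str
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..n_clusters) per sample."""
        flat = hierarchy.fcluster(self.linkage_matrix, n_clusters,
                                  criterion="maxclust")
        return pd.Series(flat, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.sample_ids)
        Z = self.linkage_matrix

        def node_height(i: int) -> float:
            return 0.0 if i < n else float(Z[i - n, 2])

        def render(i: int, parent_h: float) -> str:
            length = parent_h - node_height(i)
            if i < n:
                return f"{self.sample_ids[i]}:{length:.6g}"
            left, right = int(Z[i - n, 0]), int(Z[i - n, 1])
            h = node_height(i)
            return f"({render(left, h)},{render(right, h)}):{length:.6g}"

        root = n + len(Z) - 1
        h = node_height(root)
        left, right = int(Z[-1, 0]), int(Z[-1, 1])
        return f"({render(left, h)},{render(right, h)});"


def _canonical_leaf_order(Z: np.ndarray, sample_ids: list[str]) -> list[str]:
    """Leaf order with each merge's children sorted by smallest leaf id."""
    n = len(sample_ids)

    min_leaf: dict[int, str] = {}
    leaves: dict[int, list[int]] = {}

    def build(i: int) -> list[int]:
        if i in leaves:
            return leaves[i]
        if i < n:
            leaves[i] = [i]
            min_leaf[i] = sample_ids[i]
            return leaves[i]
        left, right = int(Z[i - n, 0]), int(Z[i - n, 1])
        l_leaves, r_leaves = build(left), build(right)
        if min_leaf[right] < min_leaf[left]:
            l_leaves, r_leaves = r_leaves, l_leaves
            min_leaf[i] = min_leaf[right]
        else:
            min_leaf[i] = min_leaf[left]
        leaves[i] = l_leaves + r_leaves
        return leaves[i]

    order = build(n + len(Z) - 1)
    return [sample_ids[i] for i in order]


def hierarchical_cluster(
    table: FeatureTable,
    metric: str = "uncentered",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples over the table's signals."""
    if table.n_samples < 2:
        raise DataError("clustering needs at least 2 samples")
    if table.n_signals == 0:
        raise DataError("clustering needs a nonempty signal set")
    if linkage not in ("average", "complete", "single"):
        raise ConfigurationError(f"unsupported linkage: {linkage!r}")
    ids = table.sample_ids
    X = table.intensities.to_numpy(dtype=float)
    D = pairwise_distance(X, ids, metric=metric)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        sample_ids=ids,
        metric=metric,
        linkage=linkage,
        leaf_order=_canonical_leaf_order(Z, ids),
    )


def branch_purity(
    dendrogram: Dendrogram,
    labels: pd.Series,
    level: float = 0.95,
) -> pd.DataFrame:
    """Class composition of the two branches at the 2-cluster cut.

    One row per (branch, class): branch size, class count, percentage and
    exact binomial CI.  Branch 1 is the branch containing the first leaf of
    the canonical leaf order.
    """
    cut = dendrogram.cut(2)
    first_branch = cut.loc[dendrogram.leaf_order[0]]
    branch_of = cut.map({first_branch: 1, 3 - first_branch: 2})
    classes = sorted(pd.unique(labels.reindex(cut.index).dropna()))
    rows = []
    for branch in (1, 2):
        members = branch_of.index[branch_of == branch]
        n = len(members)
        branch_labels = labels.reindex(members)
        for cls in classes:
            x = int((branch_labels == cls).sum())
            ci = clopper_pearson(x, n, level) if n else None
            rows.append(
                {
                    "branch": branch,
                    "class": cls,
                    "n_branch": n,
                    "count": x,
                    "percent": round_percent(100.0 * x / n) if n else None,
                    "ci_lower": ci.lower if ci else None,
                    "ci_upper": ci.upper if ci else None,
                }
            )
    return pd.DataFrame(rows).set_index(["branch", "class"])
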