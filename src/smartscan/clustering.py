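"""Similarity analysis of significant-model loadings.

All significant subset models are compared through their predictive
weight vectors w using 1 − cosine similarity as the distance and
average linkage.  The number of clusters is decided against a simulated
95% confidence limit: random loading sets of the same shape are
clustered repeatedly, giving the null distribution of merge heights
(random directions in high dimension are near-orthogonal, so null
merges sit near distance 1).  Observed merges *below* the lower 5th
percentile of that distribution express non-random similarity and fuse
models into a common cluster; merges at null-typical heights separate
them.  One single cluster therefore means that every significant model
expresses the same underlying marker pattern, while random data
dissolve into singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from smartscan.errors import SmartError


def loading_distance(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """1 − cosine similarity between two loading vectors."""
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    ni, nj = np.linalg.norm(w_i), np.linalg.norm(w_j)
    if ni == 0 or nj == 0:
        raise SmartError("cosine distance undefined for a zero loading vector")
    return float(1.0 - w_i @ w_j / (ni * nj))


@dataclass
class ClusterResult:
    """Average-linkage clustering of model loadings.

    ``n_clusters`` is the count at the simulated 95% cut height;
    ``labels`` assigns each model to its cluster.
    """

    distance_matrix: np.ndarray
    linkage: np.ndarray | None
    n_clusters: int
    cut_height: float
    labels: np.ndarray
    null_heights: np.ndarray | None = None

    def to_newick(self, names: list[str] | None = None) -> str:
        """Serialize the dendrogram as a Newick string."""
        if self.linkage is None:
            name = (names or ["model0"])[0]
            return f"{name};"
        if names is None:
            names = [f"model{i}" for i in range(len(self.labels))]
        root = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


def _merge_heights(X: np.ndarray) -> np.ndarray:
    d = pdist(X, metric="cosine")
    Z = hierarchy.linkage(d, method="average")
    return Z[:, 2]


def cluster_models(
    loadings: np.ndarray,
    n_null: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ClusterResult:
    """Cluster significant-model loading vectors and count clusters.

    Parameters
    ----------
    loadings : ndarray (models, variables)
        Predictive weight vectors of the significant models.
    n_null : int
        Replicates for the simulated confidence limit.  Each replicate
        draws a same-shaped set of independent standard-normal loading
        vectors and clusters it the same way; the pooled null merge
        heights define what "random similarity" looks like.  The
        observed tree is cut at the lower ``1 - level`` quantile of
        those heights, so only merges tighter than random directions
        would produce count as a shared pattern.
    """
    loadings = np.asarray(loadings, dtype=float)
    m = len(loadings)
    if m < 2:
        return ClusterResult(
            distance_matrix=np.zeros((m, m)), linkage=None, n_clusters=m,
            cut_height=np.nan, labels=np.zeros(m, dtype=int),
        )
    d = pdist(loadings, metric="cosine")
    Z = hierarchy.linkage(d, method="average")

    rng = np.random.default_rng(seed)
    null_heights = np.concatenate([
        _merge_heights(rng.standard_normal(loadings.shape)) for _ in range(n_null)
    ])
    cut = float(np.quantile(null_heights, 1.0 - level))
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return ClusterResult(
        distance_matrix=squareform(d), linkage=Z, n_clusters=int(labels.max()),
        cut_height=cut, labels=labels, null_heights=null_heights,
    )
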