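"""Hierarchical clustering with uncentered correlation and average linkage.

Dissimilarity between two expression profiles is 1 minus their
uncentered correlation (cosine similarity without mean-centering);
agglomeration is UPGMA (size-weighted average linkage).  Partitions are
compared with the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .normalization import ExpressionMatrix


@dataclass
class Dendrogram:
    """Merge tree: scipy-format linkage matrix plus the leaf identifiers."""

    linkage: np.ndarray  # (n-1, 4): node_a, node_b, height, cluster size
    leaf_ids: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl = node.dist - left.dist
            br = node.dist - right.dist
            return f"({walk(left)}:{bl:.6g},{walk(right)}:{br:.6g})"

        return walk(tree) + ";"


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity without mean-centering, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def dissimilarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - uncentered correlation for rows of ``profiles``."""
    norms = np.linalg.norm(profiles, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm profile")
    sim = (profiles @ profiles.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def hcluster(matrix: ExpressionMatrix, axis: str = "samples") -> Dendrogram:
    """Average-linkage agglomeration of samples (or features).

    Merge heights follow the UPGMA update (size-weighted mean of the
    constituent pairwise dissimilarities); ties are broken
    deterministically by lowest node index.
    """
    if axis == "samples":
        profiles, ids = matrix.values.T, matrix.sample_ids
    elif axis == "features":
        profiles, ids = matrix.values, matrix.feature_ids
    else:
        raise ValueError("axis must be 'samples' or 'features'")
    if len(ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    d = dissimilarity_matrix(np.asarray(profiles, dtype=float))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite dissimilarity")
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, list(ids))


def cut_tree(d: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels from removing the k-1 highest merges."""
    n = len(d.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    return hierarchy.fcluster(d.linkage, t=k, criterion="maxclust")


def cluster_concordance(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions of the same samples."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions cover different sample sets")
    return float(adjusted_rand_score(labels_a, labels_b))
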