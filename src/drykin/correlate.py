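"""Compound correlation among drying runs: standardized features, PCA
loadings, and Ward hierarchical clustering with a fixed cluster count.

The study summarises each run by its conditions (temperature, thickness)
and outcomes (Deff, Bi, hm, specific energy, hardness), standardizes the
feature matrix, and reads co-behaviour off a PCA loading plot and a
dendrogram cut into four groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from sklearn.decomposition import PCA

__all__ = ["feature_matrix", "pca_loadings", "PcaLoadings", "cluster_samples", "ClusterResult"]


def feature_matrix(samples: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Standardize the selected columns to zero mean and unit variance.

    Population scaling (ddof=0), so two samples map to exactly +-1.
    Raises on zero-variance columns, naming the offender.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    out = {}
    for col in columns:
        x = samples[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"column {col!r} contains missing values")
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=samples.index)


@dataclass(frozen=True)
class PcaLoadings:
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    degenerate: tuple[int, ...]  # components with ~zero variance


def pca_loadings(matrix: pd.DataFrame, n_components: int = 2) -> PcaLoadings:
    """Loadings of the first components of a standardized feature matrix.

    Loadings are orthonormal columns; each component's sign is fixed so its
    largest-magnitude loading is positive, making the output deterministic.
    Components with near-zero explained variance are flagged, not dropped.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least three samples")
    n_components = min(n_components, matrix.shape[1], len(matrix) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(matrix.to_numpy(dtype=float))
    comps = pca.components_.copy()  # components x features
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    degenerate = tuple(
        int(i) for i, v in enumerate(pca.explained_variance_ratio_) if v < 1e-12
    )
    loadings = pd.DataFrame(
        comps.T,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(comps.shape[0])],
    )
    return PcaLoadings(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # 0-based, relabelled by first appearance
    merge_tree: np.ndarray  # scipy linkage matrix
    n_clusters: int

    def newick(self, leaf_names=None) -> str:
        """Newick serialization of the merge tree (heights as branch lengths)."""
        root = to_tree(self.merge_tree)
        names = leaf_names if leaf_names is not None else [
            str(i) for i in range(len(self.labels))
        ]

        def render(node, parent_height) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(root, root.dist).rsplit(":", 1)[0] + ";"


def cluster_samples(matrix: pd.DataFrame, n_clusters: int = 4) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering cut at ``n_clusters``.

    Labels are renumbered in order of first appearance along the row order,
    so the output is deterministic and invariant to internal label churn.
    """
    x = matrix.to_numpy(dtype=float)
    if n_clusters > len(x):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(x)} samples")
    tree = linkage(x, method="ward", metric="euclidean")
    raw = fcluster(tree, t=n_clusters, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return ClusterResult(labels=labels, merge_tree=tree, n_clusters=n_clusters)
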