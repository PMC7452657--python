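"""Unsupervised analysis of feature tables.

The pipeline mirrors common practice for intrinsic-property datasets:
z-score each feature, reduce with PCA computed by singular value
decomposition, agglomerate hierarchically (default Ward linkage on Euclidean
distances in PC space), and pick the cluster number that maximizes the mean
silhouette coefficient.  Linkage and metric are configurable and echoed in
the result, since the choice is a convention rather than a given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .exceptions import ValidationError

__all__ = [
    "PCAModel",
    "ClusterResult",
    "fit_pca",
    "select_components",
    "hierarchical_cluster",
    "silhouette_sweep",
    "export_dendrogram",
    "tree_to_newick",
]

DEFAULT_K_RANGE = range(2, 11)


@dataclass
class PCAModel:
    """Principal components of a z-scored feature table."""

    loadings: np.ndarray  # feature x component, orthonormal columns
    scores: np.ndarray  # cell x component
    variance_explained: np.ndarray  # fractions, non-increasing
    means: np.ndarray
    sds: np.ndarray
    feature_names: tuple[str, ...]
    row_ids: tuple = ()

    def transform(self, x: np.ndarray) -> np.ndarray:
        return ((np.asarray(x, dtype=float) - self.means) / self.sds) @ self.loadings

    def cumulative_variance(self, n: int) -> float:
        return float(np.sum(self.variance_explained[:n]))


@dataclass
class ClusterResult:
    """Agglomeration tree plus flat cuts and silhouette diagnostics."""

    linkage_tree: np.ndarray  # scipy linkage matrix (n-1 x 4)
    labels_for_k: dict[int, np.ndarray]
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    optimal_k: int | None = None
    method: str = "ward"
    metric: str = "euclidean"
    row_ids: tuple = ()


def fit_pca(table: pd.DataFrame | np.ndarray, ddof: int = 1) -> PCAModel:
    """PCA by singular value decomposition of the z-scored table.

    Constant columns cannot be z-scored and raise; NaN cells raise with a
    pointer to the imputation/exclusion policy.  Sign convention: within each
    component the largest-magnitude loading is positive.
    """
    if isinstance(table, pd.DataFrame):
        num = table.select_dtypes(include=[np.number])
        names = tuple(num.columns)
        row_ids = tuple(num.index)
        x = num.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        names = tuple(f"f{i}" for i in range(x.shape[1]))
        row_ids = tuple(range(x.shape[0]))
    if x.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 rows")
    if np.isnan(x).any():
        raise ValidationError(
            "table contains NaN cells; exclude incomplete rows or impute "
            "(see the missing-feature policy) before PCA"
        )
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=ddof)
    if np.any(sds == 0):
        bad = [names[i] for i in np.nonzero(sds == 0)[0]]
        raise ValidationError(f"constant columns cannot be standardized: {bad}")
    z = (x - means) / sds

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    # Deterministic sign: largest |loading| per component made positive.
    for j in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s**2
    variance_explained = var / var.sum()
    return PCAModel(
        loadings=loadings,
        scores=scores,
        variance_explained=variance_explained,
        means=means,
        sds=sds,
        feature_names=names,
        row_ids=row_ids,
    )


def select_components(
    model: PCAModel, n: int | None = None, cum_var: float | None = None
) -> tuple[np.ndarray, float]:
    """First ``n`` PC scores (default 3) and their cumulative variance.

    Alternatively pick the smallest ``n`` reaching ``cum_var`` of total
    variance.
    """
    total = model.scores.shape[1]
    if cum_var is not None:
        if not 0 < cum_var <= 1:
            raise ValidationError("cum_var must be in (0, 1]")
        cs = np.cumsum(model.variance_explained)
        n = int(np.searchsorted(cs, cum_var - 1e-12) + 1)
    if n is None:
        n = min(3, total)
    if not 1 <= n <= total:
        raise ValidationError(f"n must be in [1, {total}], got {n}")
    return model.scores[:, :n], model.cumulative_variance(n)


def hierarchical_cluster(
    scores: np.ndarray,
    method: str = "ward",
    metric: str = "euclidean",
    k_range: range | None = None,
) -> ClusterResult:
    """Agglomerative clustering of PC scores with flat cuts for each k."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if n < 3:
        raise ValidationError("clustering needs at least 3 rows")
    k_range = k_range or DEFAULT_K_RANGE
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError(f"no valid k in {k_range} for n={n}")
    tree = linkage(scores, method=method, metric=metric)
    labels_for_k = {k: fcluster(tree, t=k, criterion="maxclust") for k in ks}
    return ClusterResult(
        linkage_tree=tree,
        labels_for_k=labels_for_k,
        method=method,
        metric=metric,
        row_ids=tuple(range(n)),
    )


def silhouette_sweep(
    scores: np.ndarray,
    result: ClusterResult,
    k_range: range | None = None,
) -> ClusterResult:
    """Mean silhouette per k (same metric as the clustering); picks optimal k.

    Ties break toward the smallest k.  Cuts that fail to produce k distinct
    clusters (exact duplicates) score 0.  Singleton clusters contribute
    silhouette 0 per the usual convention.
    """
    scores = np.asarray(scores, dtype=float)
    ks = sorted(
        k for k in (k_range or result.labels_for_k.keys()) if k in result.labels_for_k
    )
    metric = result.metric if result.method != "ward" else "euclidean"
    sil: dict[int, float] = {}
    for k in ks:
        labels = result.labels_for_k[k]
        if len(np.unique(labels)) < 2:
            sil[k] = 0.0
        else:
            sil[k] = float(silhouette_score(scores, labels, metric=metric))
    result.silhouette_by_k = sil
    result.optimal_k = max(ks, key=lambda k: (sil[k], -k))
    return result


def _newick_recursive(tree: np.ndarray, leaf_names: list[str]) -> str:
    n = tree.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    for i in range(tree.shape[0]):
        heights[n + i] = float(tree[i, 2])

    def node_str(idx: int) -> str:
        if idx < n:
            return leaf_names[idx]
        row = tree[idx - n]
        left, right = int(row[0]), int(row[1])
        h = heights[idx]
        return (
            f"({node_str(left)}:{h - heights[left]:g},"
            f"{node_str(right)}:{h - heights[right]:g})"
        )

    root = n + tree.shape[0] - 1
    return node_str(root) + ";"


def tree_to_newick(tree: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Newick string with branch lengths taken from merge heights."""
    n = tree.shape[0] + 1
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]
    if len(leaf_names) != n:
        raise ValidationError(f"need {n} leaf names, got {len(leaf_names)}")
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        return _newick_recursive(tree, list(leaf_names))
    finally:
        sys.setrecursionlimit(old)


def export_dendrogram(
    result: ClusterResult,
    path: str,
    leaf_names: list[str] | None = None,
    render: str | None = None,
) -> str:
    """Write the tree as Newick text; optionally render an image alongside.

    Returns the Newick string.  ``render`` is an image path (.png/.pdf/.svg).
    """
    newick = tree_to_newick(result.linkage_tree, leaf_names)
    with open(path, "w") as fh:
        fh.write(newick + "\n")
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        _scipy_dendrogram(result.linkage_tree, labels=leaf_names, ax=ax)
        ax.set_ylabel(f"{result.method} merge height")
        fig.tight_layout()
        fig.savefig(render, dpi=120)
        plt.close(fig)
    return newick
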