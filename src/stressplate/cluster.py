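"""Endpoint and time-course ("cubic") hierarchical clustering.

Endpoint clustering treats one row per entity (treatment or reporter) over
a feature vector.  Time-course clustering keeps the extra time dimension:
all pairwise distances between the 24-point curves of two entities are
computed per feature (or per reporter), the resulting per-slice distance
matrices are stacked into a :class:`DistanceCube`, and the mean over the
stack reduces the cube back to a 2-D matrix that feeds the agglomerative
clustering.

Metrics: ``euclidean`` (default), ``maximum`` (Chebyshev) and ``pearson``
(1 − r).  Linkages: ``complete`` (default), ``ward``, ``average``.  Named
presets reproduce the published metric/linkage variants:
``fig4`` = pearson/ward endpoint, ``fig6`` = maximum/complete time-course,
``fig8`` = euclidean/ward time-course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "pearson", "maximum")
LINKAGES = ("complete", "ward", "average")

#: Published metric/linkage presets: (metric, linkage).
PRESETS = {
    "fig4": ("pearson", "ward"),
    "fig6": ("maximum", "complete"),
    "fig8": ("euclidean", "ward"),
}


class ClusterError(ValueError):
    """Raised on invalid clustering inputs."""


@dataclass
class ClusterResult:
    """Agglomeration output: linkage matrix, labels and leaf order."""

    linkage: np.ndarray
    labels: list[str]
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def flat_clusters(self, n_clusters: int | None = None, height: float | None = None) -> pd.Series:
        """Flat cluster ids per label, by cluster count or height cut."""
        if (n_clusters is None) == (height is None):
            raise ClusterError("give exactly one of n_clusters or height")
        if n_clusters is not None:
            assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        else:
            assign = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram in Newick text, branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def pairwise_distances(matrix: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Square distance matrix between rows under the named metric."""
    x = np.asarray(matrix, dtype=float)
    if metric == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if metric == "maximum":
        return squareform(pdist(x, metric="chebyshev"))
    if metric == "pearson":
        return squareform(pdist(x, metric="correlation"))
    raise ClusterError(f"unknown metric {metric!r}; choose from {METRICS}")


def _check_square(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ClusterError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ClusterError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ClusterError("distance matrix needs a zero diagonal and no negatives")
    return d


def _linkage_from_distance(dist: np.ndarray, method: str) -> np.ndarray:
    if method not in LINKAGES:
        raise ClusterError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    return hierarchy.linkage(squareform(_check_square(dist), checks=False), method=method)


def endpoint_cluster(
    matrix: pd.DataFrame | np.ndarray,
    metric: str = "euclidean",
    linkage: str = "complete",
    labels: list[str] | None = None,
    preset: str | None = None,
) -> ClusterResult:
    """Agglomerative clustering of an entities × features matrix.

    Missing values are imputed by zero (logged) — after normalization a
    missing condition contributes no response.  Rows are sorted by label
    before clustering so that permuting the input never changes the result.
    """
    if preset is not None:
        metric, linkage = PRESETS[preset]
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in (labels if labels is not None else range(len(x)))]
    if len(x) < 2:
        raise ClusterError("clustering needs at least 2 entities")
    n_missing = int(np.isnan(x).sum())
    if n_missing:
        logger.info("endpoint_cluster: imputing %d missing values by 0", n_missing)
        x = np.nan_to_num(x, nan=0.0)
    order = np.argsort(np.asarray(labels, dtype=object))
    x, labels = x[order], [labels[i] for i in order]
    z = _linkage_from_distance(pairwise_distances(x, metric), linkage)
    return ClusterResult(linkage=z, labels=labels, metric=metric, method=linkage)


@dataclass
class DistanceCube:
    """Per-slice pairwise distance matrices plus their mean reduction.

    ``stack`` has shape (n_slices, n_entities, n_entities); slices are
    per-feature (when comparing treatments) or per-reporter.  Pairs missing
    from a slice are NaN there and the mean is taken over available slices.
    """

    entities: list[str]
    slice_names: list[str]
    stack: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.entities)
        if self.stack.shape != (len(self.slice_names), n, n):
            raise ClusterError("distance cube shape does not match its labels")
        for k, name in enumerate(self.slice_names):
            s = self.stack[k]
            valid = ~np.isnan(s)
            if not np.allclose(
                np.where(valid & valid.T, s, 0), np.where(valid & valid.T, s.T, 0), atol=1e-10
            ):
                raise ClusterError(f"slice {name!r} is not symmetric")

    @property
    def mean_matrix(self) -> np.ndarray:
        counts = np.sum(~np.isnan(self.stack), axis=0)
        off_diag = ~np.eye(len(self.entities), dtype=bool)
        if np.any(counts[off_diag] == 0):
            raise ClusterError("some entity pair has no distance in any slice")
        if np.any(counts < len(self.slice_names)):
            logger.info(
                "distance cube: %d pairs averaged over fewer than %d slices",
                int(np.sum(counts < len(self.slice_names)) // 2),
                len(self.slice_names),
            )
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(self.stack, axis=0)
        np.fill_diagonal(mean, 0.0)
        return mean


def curve_distance_cube(
    normalized: pd.DataFrame,
    compare_axis: str = "treatment",
    metric: str = "euclidean",
    value_col: str = "value",
) -> DistanceCube:
    """Pairwise time-curve distances per slice, for time-course clustering.

    ``compare_axis='treatment'`` compares treatments with one slice per
    (reporter, feature); ``'reporter'`` compares reporters with one slice
    per treatment.  Replicate curves are averaged per entity and slice
    before distances are taken over the resampled 24-vectors.
    """
    if compare_axis not in ("treatment", "reporter"):
        raise ClusterError("compare_axis must be 'treatment' or 'reporter'")
    slice_keys = ["reporter", "feature"] if compare_axis == "treatment" else ["treatment"]
    entities = sorted(normalized[compare_axis].astype(str).unique())
    idx = {e: i for i, e in enumerate(entities)}
    slices = []
    names = []
    for key, grp in normalized.groupby(slice_keys, sort=True):
        name = key if isinstance(key, str) else "/".join(str(k) for k in key)
        mean_curves = (
            grp.groupby([compare_axis, "time_h"], sort=True)[value_col].mean().unstack()
        )
        mat = np.full((len(entities), len(entities)), np.nan)
        present = [str(e) for e in mean_curves.index]
        sub = pairwise_distances(mean_curves.to_numpy(), metric)
        for a, ea in enumerate(present):
            for b, eb in enumerate(present):
                mat[idx[ea], idx[eb]] = sub[a, b]
        slices.append(mat)
        names.append(name)
    return DistanceCube(entities=entities, slice_names=names, stack=np.stack(slices))


def cubic_cluster(
    cube: DistanceCube | np.ndarray,
    linkage: str = "complete",
    labels: list[str] | None = None,
    n_clusters: int | None = None,
    height: float | None = None,
) -> tuple[ClusterResult, pd.Series | None]:
    """Hierarchical clustering on a (mean-reduced) precomputed distance matrix.

    Accepts a :class:`DistanceCube` (its mean matrix is used) or a square
    distance matrix directly.  Returns the clustering and, when a cut is
    requested, the flat cluster assignment.
    """
    if isinstance(cube, DistanceCube):
        dist = cube.mean_matrix
        labels = cube.entities
    else:
        dist = _check_square(cube)
        labels = [str(i) for i in (labels if labels is not None else range(len(dist)))]
    z = _linkage_from_distance(dist, linkage)
    result = ClusterResult(linkage=z, labels=list(labels), metric="precomputed", method=linkage)
    flat = None
    if n_clusters is not None or height is not None:
        flat = result.flat_clusters(n_clusters=n_clusters, height=height)
    return result, flat
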