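"""Community structure: standardization, Euclidean distances, Ward clustering.

Transects (or trawl stations) are compared on their taxon-count vectors.
Counts are centered and scaled per taxon (column z-scores), pairwise
Euclidean distances are computed, and groups are built by Ward's minimum
variance method: at each step the pair of clusters whose merge least
increases the total within-cluster sum of squares is joined.

Merge heights are reported as that increase in within-cluster sum of squares,
``delta(A, B) = n_A * n_B / (n_A + n_B) * ||c_A - c_B||**2`` for cluster
centroids ``c`` and sizes ``n``.  (The other common convention reports
``sqrt(2 * delta)``; the two orderings are identical.)  Ties in the minimum
merge cost are broken deterministically.

Dendrograms can be exported as Newick with branch lengths derived from merge
heights, and cut into ``k`` groups.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .annotations import DEFAULT_SEDIMENT_CLASSES, FrameRecord

__all__ = [
    "Dendrogram",
    "standardize",
    "euclidean_distances",
    "ward_cluster",
    "cut_tree",
    "to_newick",
    "sediment_composition",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence over ``len(labels)`` leaves.

    ``merges[i] = (a, b)`` joins clusters ``a`` and ``b`` (ids < n are leaves,
    ids >= n refer to earlier merges, following the scipy linkage convention);
    ``heights[i]`` is the within-cluster sum-of-squares increase of that merge.
    """

    merges: np.ndarray
    heights: np.ndarray
    labels: tuple[str, ...]
    _linkage: np.ndarray  # scipy-scale linkage matrix, kept for tree utilities

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sample sd 1 (ddof=1).

    Zero-variance columns carry no between-group information and are dropped
    with a warning.  Requires at least two rows.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 rows")
    m = matrix.astype(float)
    sd = m.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}", stacklevel=2)
        m = m.drop(columns=dead)
        sd = sd.drop(index=dead)
    return (m - m.mean()) / sd


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise Euclidean row distances."""
    m = matrix.astype(float)
    if m.isna().any().any():
        raise ValueError("distance computation requires no missing values")
    d = squareform(pdist(m.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


def ward_cluster(data: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Ward minimum-variance agglomerative clustering.

    ``data`` is a (groups x features) matrix — a DataFrame keeps its index as
    leaf labels — or a precomputed square/condensed Euclidean distance
    matrix.  Heights are in within-cluster sum-of-squares units and are
    non-decreasing.
    """
    labels: tuple[str, ...]
    if isinstance(data, pd.DataFrame):
        square = data.shape[0] == data.shape[1] and np.allclose(
            data.to_numpy(), data.to_numpy().T
        ) and np.allclose(np.diag(data.to_numpy()), 0)
        if square and data.index.equals(data.columns):
            obs = squareform(data.to_numpy(), checks=False)
        else:
            obs = data.to_numpy(dtype=float)
        labels = tuple(str(i) for i in data.index)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:  # condensed distances
            obs = arr
            n = int(round((1 + np.sqrt(1 + 8 * len(arr))) / 2))
            labels = tuple(str(i) for i in range(n))
        else:
            obs = arr
            labels = tuple(str(i) for i in range(arr.shape[0]))
    if not np.all(np.isfinite(np.asarray(obs, dtype=float))):
        raise ValueError("non-finite values in clustering input")
    if (obs.ndim == 2 and obs.shape[0] < 2) or (obs.ndim == 1 and len(obs) < 1):
        raise ValueError("need at least 2 items to cluster")

    Z = hierarchy.linkage(obs, method="ward")
    # scipy reports sqrt(2 * delta-ESS); convert to the sum-of-squares scale
    heights = Z[:, 2] ** 2 / 2.0
    return Dendrogram(
        merges=Z[:, :2].astype(int),
        heights=heights,
        labels=labels,
        _linkage=Z,
    )


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut into exactly ``k`` groups by undoing the ``k - 1`` highest merges.

    Returns group ids (0..k-1) indexed by leaf label.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    grp = hierarchy.cut_tree(dendrogram._linkage, n_clusters=k).ravel()
    return pd.Series(grp, index=list(dendrogram.labels), name="cluster")


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths from merge heights.

    A node merged at height ``h`` hangs below its parent by ``h_parent - h``
    (leaves sit at height 0), so root-to-leaf path lengths equal the root
    merge height.
    """
    tree = hierarchy.to_tree(dendrogram._linkage)
    n = dendrogram.n_leaves
    heights = dendrogram.heights

    def node_height(node) -> float:
        return 0.0 if node.is_leaf() else float(heights[node.get_id() - n])

    def render(node, parent_h: float) -> str:
        bl = parent_h - node_height(node)
        if node.is_leaf():
            return f"{dendrogram.labels[node.get_id()]}:{bl:.6g}"
        left = render(node.get_left(), node_height(node))
        right = render(node.get_right(), node_height(node))
        return f"({left},{right}):{bl:.6g}"

    root_h = node_height(tree)
    left = render(tree.get_left(), root_h)
    right = render(tree.get_right(), root_h)
    return f"({left},{right});"


def sediment_composition(
    records: Sequence[FrameRecord],
    classes: tuple[str, ...] = DEFAULT_SEDIMENT_CLASSES,
) -> pd.DataFrame:
    """Mean sediment proportions per transect over frames with sediment data.

    Per-frame visual percentages are averaged within each transect and
    renormalized to sum to one.  Transects with no sediment annotations get a
    NaN row.  Returns a (transect x sediment class) DataFrame.
    """
    groups: dict[str, list[FrameRecord]] = {}
    for r in records:
        groups.setdefault(r.transect_id, []).append(r)

    rows = {}
    for gid in sorted(groups):
        frames = [r for r in groups[gid] if r.sediment_pct]
        if not frames:
            rows[gid] = {c: np.nan for c in classes}
            continue
        means = {
            c: float(np.mean([f.sediment_pct.get(c, 0.0) for f in frames])) for c in classes
        }
        total = sum(means.values())
        if total == 0:
            rows[gid] = {c: np.nan for c in classes}
        else:
            rows[gid] = {c: v / total for c, v in means.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(classes))
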