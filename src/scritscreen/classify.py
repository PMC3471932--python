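"""Unsupervised classification of SCRIT vectors into mechanistic groups.

Compound similarity is the Pearson distance 1 - r between response
fingerprints (Euclidean distance is used in the single-dose primary screen).
Replicates are clustered as separate items; agglomerative clustering
(average linkage by default) and classical multidimensional scaling provide
the two standard views of the distance structure, and flat clusters are
labelled by matching their medoid against reference fingerprints of the five
mechanistic groups:

    I   direct mitochondrial toxins
    II  glucose-independent toxins
    III glucose-dependent toxins
    IV  inactive / non-toxic compounds
    V   uncouplers (FCCP-like)

Clusters too far from every reference are labelled ``other`` for manual
review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ContractError, DomainError
from .scrit import SCRITVector

__all__ = [
    "NEAR_CONSTANT_VAR",
    "DistanceMatrix",
    "ClusterResult",
    "pearson_distance",
    "distance_matrix",
    "hierarchical_cluster",
    "mds_embed",
    "assign_groups",
    "dendrogram_newick",
]

#: Component variance below which a vector counts as constant (degenerate r).
NEAR_CONSTANT_VAR = 1e-6


def pearson_distance(u, v) -> float:
    """Pearson distance 1 - r in [0, 2].

    A (near-)constant vector has no defined correlation; by documented
    convention the distance is then 1 (the value for uncorrelated vectors),
    with a warning -- inactive-compound fingerprints can be near-constant.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ContractError("vectors must be 1-D and of equal length")
    if len(u) < 3:
        raise ContractError("Pearson distance needs at least 3 components")
    if np.var(u) < NEAR_CONSTANT_VAR or np.var(v) < NEAR_CONSTANT_VAR:
        warnings.warn(
            "Pearson distance of a near-constant vector is undefined; using 1.0",
            stacklevel=2,
        )
        return 1.0
    r = float(np.corrcoef(u, v)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 2.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with item ids and the metric used."""

    ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ContractError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ContractError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def distance_matrix(
    vectors: Sequence[SCRITVector], metric: str = "pearson"
) -> DistanceMatrix:
    """All pairwise distances between SCRIT vectors (``pearson`` or ``euclidean``)."""
    if len(vectors) < 2:
        raise ContractError("need at least two vectors")
    shapes = {len(v) for v in vectors}
    indices = {v.index for v in vectors}
    if len(shapes) > 1 or len(indices) > 1:
        raise ContractError("vectors have mixed shapes or component indices")
    n = len(vectors)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "pearson":
                d = pearson_distance(vectors[i].values, vectors[j].values)
            elif metric == "euclidean":
                d = float(np.linalg.norm(vectors[i].values - vectors[j].values))
            else:
                raise DomainError(f"unknown metric {metric!r}")
            m[i, j] = m[j, i] = d
    ids = [v.item_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ContractError("duplicate item ids among vectors")
    return DistanceMatrix(ids=ids, matrix=m, metric=metric)


@dataclass
class ClusterResult:
    """Dendrogram, flat assignment, and (optionally) group labels."""

    ids: list[str]
    linkage_matrix: np.ndarray
    linkage_method: str
    flat_labels: dict[str, int]
    n_flat_clusters: int
    cut_height: float
    group_labels: dict[str, str] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.flat_labels.items() if c == cluster]


def hierarchical_cluster(
    D: DistanceMatrix,
    linkage: str = "average",
    n_clusters: int = 5,
) -> ClusterResult:
    """Agglomerative clustering of a distance matrix.

    The flat partition cuts the dendrogram at the smallest height yielding at
    least *n_clusters* clusters (the screen's visual cut is replaced by this
    deterministic rule; the count is configurable).  Merge heights are
    non-decreasing for the supported linkages.
    """
    Z = hierarchy.linkage(D.condensed(), method=linkage)
    n = len(D.ids)
    k = min(n_clusters, n)
    heights = Z[:, 2]
    # cutting strictly below the (n-k)-th merge (0-based) leaves k clusters
    cut = 0.0 if k >= n else float(heights[n - k - 1])
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        ids=list(D.ids),
        linkage_matrix=Z,
        linkage_method=linkage,
        flat_labels={i: int(c) for i, c in zip(D.ids, flat)},
        n_flat_clusters=int(flat.max()),
        cut_height=cut,
    )


def mds_embed(D: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Deterministic eigendecomposition of the double-centred squared-distance
    matrix; coordinates are centred, and each axis' sign is fixed so that
    its largest-magnitude coordinate is positive.  If fewer than *dims*
    positive eigenvalues exist the embedding is reduced with a warning.
    """
    if dims < 1:
        raise DomainError("dims must be >= 1")
    d2 = D.matrix**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = int(np.sum(eigval > 1e-10))
    if positive < dims:
        warnings.warn(
            f"only {positive} positive eigenvalue(s); reducing embedding "
            f"from {dims} to {positive} dimension(s)",
            stacklevel=2,
        )
        dims = max(positive, 1)
    coords = eigvec[:, :dims] * np.sqrt(np.maximum(eigval[:dims], 0.0))
    for j in range(coords.shape[1]):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=D.ids, columns=[f"mds{j + 1}" for j in range(coords.shape[1])]
    )


def assign_groups(
    cluster: ClusterResult,
    vectors: Sequence[SCRITVector],
    references: Mapping[str, SCRITVector],
    distance_ceiling: float = 0.8,
) -> dict[str, str]:
    """Label every clustered item with a mechanistic group.

    Each flat cluster's medoid (the member minimising its summed Pearson
    distance to the other members) is compared with every reference
    fingerprint; the cluster takes the nearest reference's group, or
    ``other`` if the nearest reference is farther than *distance_ceiling* --
    those clusters go to manual review.  Results land in
    ``cluster.group_labels`` as well as being returned.
    """
    if not references:
        raise ContractError("no reference fingerprints supplied")
    by_id = {v.item_id: v for v in vectors}
    missing = [i for i in cluster.ids if i not in by_id]
    if missing:
        raise ContractError(f"vectors missing for clustered items: {missing[:5]}")
    ref_items = list(references.items())
    labels: dict[str, str] = {}
    for c in range(1, cluster.n_flat_clusters + 1):
        members = cluster.members(c)
        if not members:
            continue
        if len(members) == 1:
            medoid = by_id[members[0]]
        else:
            vals = [by_id[m].values for m in members]
            totals = [
                sum(pearson_distance(vals[i], vals[j]) for j in range(len(vals)) if j != i)
                for i in range(len(vals))
            ]
            medoid = by_id[members[int(np.argmin(totals))]]
        dists = [
            pearson_distance(medoid.values, ref.values) for _, ref in ref_items
        ]
        best = int(np.argmin(dists))
        group = ref_items[best][0] if dists[best] <= distance_ceiling else "other"
        for m in members:
            labels[m] = group
    cluster.group_labels = labels
    return labels


def dendrogram_newick(cluster: ClusterResult) -> str:
    """Serialise the dendrogram as a Newick string with merge-height branch lengths."""
    tree = hierarchy.to_tree(cluster.linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            name = cluster.ids[node.id].replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
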