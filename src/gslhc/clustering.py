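"""Pearson-distance average-linkage clustering and clade extraction.

Distances are d = 1 - r (Pearson correlation), in [0, 2]; anticorrelated
profiles are maximally distant, so drugs acting in opposite directions do
not cluster.  Linkage is UPGMA (unweighted average): the distance between
two clusters is the mean of all cross-pair distances, and merge heights are
monotone non-decreasing.  Ties are broken by the lexicographically smallest
member id so that clustering a permuted input reproduces the same tree.

A clade at correlation threshold ``c`` is a subtree whose internal merges
all lie at height <= 1 - c (cophenetic reading of "correlation above a
threshold").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import Dendrogram, ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "Clade",
    "ZeroVarianceError",
    "pearson_distance",
    "average_linkage",
    "two_way_cluster",
    "extract_clade",
]


class ZeroVarianceError(ValueError):
    """Pearson correlation undefined for constant profiles."""

    def __init__(self, ids: Sequence[str]):
        super().__init__(
            f"zero-variance items (correlation undefined): {list(ids)[:10]}"
        )
        self.ids = tuple(ids)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Pearson-distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(ids) != values.shape[0]:
            raise ValueError("id count does not match matrix size")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > 1e-10:
            raise ValueError("diagonal must be zero")
        if values.size and (
            values.min() < -1e-10 or values.max() > 2.0 + 1e-10
        ):
            raise ValueError("Pearson distances must lie in [0, 2]")
        values = np.clip((values + values.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(values, 0.0)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Clade:
    """A dendrogram subtree selected at a correlation threshold."""

    members: frozenset[str]
    max_internal_height: float
    qualifying: bool  # False when no subtree met the threshold


def pearson_distance(
    matrix: ExpressionMatrix, axis: str = "columns"
) -> DistanceMatrix:
    """Pairwise d = 1 - Pearson(r) between rows or columns of a matrix.

    Zero-variance items are an error (in an enrichment-score matrix they
    signal a degenerate build), reported with the offending ids.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if axis == "rows":
        vectors = matrix.values
        ids = matrix.row_ids
    else:
        vectors = matrix.values.T
        ids = matrix.col_ids
    if vectors.shape[0] < 2:
        raise ValueError("need at least two items to compute distances")
    variances = vectors.var(axis=1)
    if np.any(variances == 0.0):
        bad = [ids[i] for i in np.flatnonzero(variances == 0.0)]
        raise ZeroVarianceError(bad)
    corr = np.corrcoef(vectors)
    return DistanceMatrix(ids=tuple(ids), values=1.0 - corr)


def _merge_key(min_a: str, min_b: str) -> tuple[str, str]:
    return (min_a, min_b) if min_a <= min_b else (min_b, min_a)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a distance matrix.

    Cross-cluster distances are maintained with the Lance-Williams update
    for the unweighted average, which is algebraically the mean of all
    cross-pair distances.  Among equally close pairs the one whose smallest
    member id sorts first (then the other member id) is merged.
    """
    n = dm.n
    if n == 1:
        return Dendrogram(leaves=dm.ids, merges=())
    work = dm.values.copy()
    active = list(range(n))
    node_of = {i: i for i in range(n)}  # slot -> dendrogram node id
    size = {i: 1 for i in range(n)}
    min_leaf = {i: dm.ids[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    INF = np.inf
    mask = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(mask, True)

    for step in range(n - 1):
        masked = np.where(mask, INF, work)
        dmin = masked.min()
        pairs = np.argwhere(masked == dmin)
        pairs = pairs[pairs[:, 0] < pairs[:, 1]]
        best = min(
            (tuple(p) for p in pairs),
            key=lambda p: _merge_key(min_leaf[p[0]], min_leaf[p[1]]),
        )
        i, j = best
        left, right = node_of[i], node_of[j]
        if min_leaf[j] < min_leaf[i]:
            left, right = right, left
        merges.append((left, right, float(dmin)))
        # Lance-Williams unweighted-average update into slot i
        ni, nj = size[i], size[j]
        new_row = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = 0.0
        mask[j, :] = True
        mask[:, j] = True
        node_of[i] = n + step
        size[i] = ni + nj
        min_leaf[i] = min(min_leaf[i], min_leaf[j])

    return Dendrogram(leaves=dm.ids, merges=tuple(merges))


def _flat_dendrogram(ids: Sequence[str]) -> Dendrogram:
    """All-zero-height caterpillar in lexicographic order (degenerate axis)."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    merges = []
    node = order[0]
    for k, nxt in enumerate(order[1:]):
        merges.append((node, nxt, 0.0))
        node = len(ids) + k
    return Dendrogram(leaves=tuple(ids), merges=tuple(merges))


def two_way_cluster(
    matrix: ExpressionMatrix,
) -> tuple[Dendrogram, Dendrogram, ExpressionMatrix]:
    """Cluster rows and columns independently; reorder the matrix by both.

    A single-row (or single-column) axis yields a trivial one-leaf tree on
    that axis.  When one axis has a single item, the other axis's profiles
    are scalars and correlation is undefined; those items are treated as
    indistinguishable and joined in a flat zero-height tree.
    """

    def axis_tree(ids: tuple[str, ...], vector_length: int, axis: str) -> Dendrogram:
        if len(ids) == 1:
            return Dendrogram(leaves=ids, merges=())
        if vector_length < 2:
            return _flat_dendrogram(ids)
        return average_linkage(pearson_distance(matrix, axis=axis))

    row_tree = axis_tree(matrix.row_ids, matrix.shape[1], "rows")
    col_tree = axis_tree(matrix.col_ids, matrix.shape[0], "columns")
    reordered = matrix.subset_rows(list(row_tree.leaf_order())).subset_cols(
        list(col_tree.leaf_order())
    )
    return row_tree, col_tree, reordered


def extract_clade(
    dendrogram: Dendrogram,
    query_ids: Iterable[str],
    corr_threshold: float = 0.9,
) -> Clade:
    """Maximal subtree containing every query id with merges above a correlation.

    The subtree must contain all query leaves and have every internal merge
    at height <= 1 - corr_threshold (equivalently cophenetic correlation
    >= corr_threshold).  Under the ultrametric this reduces to: the lowest
    common ancestor of the queries must already satisfy the height bound,
    and the clade is grown root-ward while the bound holds.  If no subtree
    qualifies the query ids are returned alone with ``qualifying=False``.
    """
    query = sorted(set(str(q) for q in query_ids))
    if not query:
        raise ValueError("query_ids must be nonempty")
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must lie in (0, 1)")
    leaf_index = {name: i for i, name in enumerate(dendrogram.leaves)}
    unknown = [q for q in query if q not in leaf_index]
    if unknown:
        raise KeyError(f"unknown query ids: {unknown[:5]}")

    h_max = 1.0 - corr_threshold
    parents = dendrogram.parents
    heights = dendrogram.node_heights

    # lowest common ancestor: ascend from one query leaf until the subtree
    # covers every query id
    lca = leaf_index[query[0]]
    while not set(query) <= dendrogram.leaf_names(lca):
        lca = parents[lca]

    if heights[lca] > h_max + 1e-12:
        return Clade(
            members=frozenset(query),
            max_internal_height=float(heights[lca]),
            qualifying=False,
        )
    node = lca
    while parents[node] != -1 and heights[parents[node]] <= h_max + 1e-12:
        node = parents[node]
    return Clade(
        members=dendrogram.leaf_names(node),
        max_internal_height=float(heights[node]),
        qualifying=True,
    )
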