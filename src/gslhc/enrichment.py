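"""Ranking and Kolmogorov-Smirnov enrichment scores.

The scalar kernel :func:`ks_enrichment_score` measures whether a set of
features concentrates at the top (positive score) or bottom (negative score)
of a profile ranked in descending order.  The same kernel serves two levels
of the analysis:

* tag level — a gene set queried against one instance's ranked log-ratios,
  producing a tag x instance enrichment-score matrix;
* drug level — a drug's treatment instances queried against the ranked
  per-instance scores of one tag (the vector Vd), producing a tag x drug
  connectivity-score matrix.

With ``weight_exponent = 0`` (the default) the score is the classic
two-sided KS statistic: with set positions ``V(1) < ... < V(t)`` in a ranked
list of ``N``,

    a = max_j ( j/t - V(j)/N ),   b = max_j ( V(j)/N - (j-1)/t )

and the score is ``a`` if ``a >= b`` else ``-b``, always in [-1, 1].  With
``weight_exponent = w > 0`` the GSEA-style weighted running sum is used: hit
increments ``|score|^w`` normalized by their total, miss decrement
``1/(N - t)``, score = the maximum-magnitude deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_MIN_TAG_SIZE,
    ExpressionMatrix,
    GeneSetCollection,
    InstanceAnnotation,
    SymbolMap,
    map_tag_to_universe,
)

__all__ = [
    "RankedProfile",
    "EmptyIntersectionError",
    "rank_profile",
    "ks_enrichment_score",
    "ks_from_positions",
    "ks_from_position_matrix",
    "TagEsBuild",
    "tag_instance_es_matrix",
    "average_by_drug",
    "drug_level_es",
    "drug_es_matrix",
    "top_variance_select",
]


class EmptyIntersectionError(ValueError):
    """The query set shares no members with the ranked universe."""


@dataclass(frozen=True)
class RankedProfile:
    """A feature universe sorted by descending score (stable on ties)."""

    ordered_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.ordered_ids) != scores.shape[0]:
            raise ValueError("ordered_ids and scores must have equal length")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")

    @property
    def N(self) -> int:
        return len(self.ordered_ids)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 1-based rank positions of ``members`` (silently drops absentees)."""
        try:
            lookup = self._lookup
        except AttributeError:
            lookup = {g: i for i, g in enumerate(self.ordered_ids)}
            object.__setattr__(self, "_lookup", lookup)
        pos = sorted(lookup[m] + 1 for m in members if m in lookup)
        return np.asarray(pos, dtype=np.intp)


def rank_profile(scores: Mapping[str, float] | pd.Series) -> RankedProfile:
    """Rank features by descending score; ties keep the original input order."""
    if isinstance(scores, pd.Series):
        ids = [str(i) for i in scores.index]
        values = scores.to_numpy(dtype=float)
    else:
        ids = [str(k) for k in scores.keys()]
        values = np.asarray(list(scores.values()), dtype=float)
    if len(ids) < 2:
        raise ValueError("need at least two features to rank")
    if not np.isfinite(values).all():
        bad = ids[int(np.argmax(~np.isfinite(values)))]
        raise ValueError(f"non-finite score for feature {bad!r}")
    order = np.argsort(-values, kind="stable")
    return RankedProfile(
        ordered_ids=tuple(ids[i] for i in order), scores=values[order]
    )


# ---------------------------------------------------------------------------
# KS kernel
# ---------------------------------------------------------------------------


def ks_from_positions(positions: np.ndarray, n: int) -> float:
    """Classic two-sided KS score from sorted 1-based hit positions."""
    pos = np.asarray(positions, dtype=float)
    t = pos.shape[0]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a) if a >= b else float(-b)


def ks_from_position_matrix(positions: np.ndarray, n: int, axis: int = 1) -> np.ndarray:
    """Vectorized KS scores for a batch of position sets.

    ``positions`` holds 1-based positions, one set per slice along ``axis``
    (need not be sorted).  Returns one score per set.
    """
    pos = np.sort(np.asarray(positions, dtype=float), axis=axis)
    t = pos.shape[axis]
    shape = [1, 1]
    shape[axis] = t
    j = np.arange(1, t + 1, dtype=float).reshape(shape)
    a = np.max(j / t - pos / n, axis=axis)
    b = np.max(pos / n - (j - 1) / t, axis=axis)
    return np.where(a >= b, a, -b)


def _weighted_es(rp: RankedProfile, hit_mask: np.ndarray, w: float) -> float:
    """GSEA-style weighted running-sum score (used when weight_exponent > 0)."""
    n = rp.N
    t = int(hit_mask.sum())
    weights = np.abs(rp.scores) ** w
    hit_total = weights[hit_mask].sum()
    if hit_total == 0.0:
        # all hit scores are exactly zero; fall back to unweighted increments
        steps = np.where(hit_mask, 1.0 / t, -1.0 / (n - t))
    else:
        steps = np.where(hit_mask, weights / hit_total, -1.0 / (n - t))
    running = np.cumsum(steps)
    k = int(np.argmax(np.abs(running)))
    return float(np.clip(running[k], -1.0, 1.0))


def ks_enrichment_score(
    rp: RankedProfile,
    members: Iterable[str],
    weight_exponent: float = 0.0,
) -> float:
    """Enrichment score of ``members`` within a ranked profile; in [-1, 1].

    Members absent from the universe are ignored; an empty intersection
    raises :class:`EmptyIntersectionError` and a set covering the whole
    universe raises ``ValueError`` (the miss term is undefined).
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    pos = rp.positions(members)
    t = pos.shape[0]
    if t == 0:
        raise EmptyIntersectionError(
            "query set has no members in the ranked universe"
        )
    if t == rp.N:
        raise ValueError("query set must be smaller than the universe")
    if weight_exponent == 0.0:
        return ks_from_positions(pos, rp.N)
    hit_mask = np.zeros(rp.N, dtype=bool)
    hit_mask[pos - 1] = True
    return _weighted_es(rp, hit_mask, weight_exponent)


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def _rank_position_matrix(values: np.ndarray, axis: int) -> np.ndarray:
    """1-based descending-rank positions along ``axis`` (stable on ties)."""
    order = np.argsort(-values, axis=axis, kind="stable")
    ranks = np.empty_like(order)
    ar = np.arange(1, values.shape[axis] + 1, dtype=np.intp)
    if axis == 0:
        np.put_along_axis(ranks, order, ar[:, None], axis=0)
    else:
        np.put_along_axis(ranks, order, ar[None, :], axis=1)
    return ranks


@dataclass(frozen=True)
class TagEsBuild:
    """Result of a tag x target enrichment-score matrix build."""

    matrix: ExpressionMatrix
    exclusions: dict[str, str]  # tag name -> reason


def tag_instance_es_matrix(
    expr: ExpressionMatrix,
    tags: GeneSetCollection,
    symbol_map: SymbolMap | None = None,
    *,
    min_tag_size: int = DEFAULT_MIN_TAG_SIZE,
    weight_exponent: float = 0.0,
) -> TagEsBuild:
    """Build the tag x instance (or tag x drug) enrichment-score matrix.

    Each column of ``expr`` is ranked descending and every surviving tag is
    scored against it.  Tags whose mapped membership falls below
    ``min_tag_size`` (or covers the whole universe) are dropped and listed in
    the exclusion report; zero surviving tags is an error.
    """
    n, m = expr.shape
    exclusions: dict[str, str] = {}
    mapped: list[tuple[str, np.ndarray]] = []
    row_lookup = {r: i for i, r in enumerate(expr.row_ids)}
    for gs in tags:
        mt = map_tag_to_universe(gs, symbol_map, expr.row_ids, min_tag_size)
        if mt.flagged:
            exclusions[gs.name] = (
                f"mapped size {len(mt.members)} < min_tag_size {min_tag_size}"
            )
            continue
        if len(mt.members) >= n:
            exclusions[gs.name] = "mapped members cover the whole universe"
            continue
        idx = np.fromiter(
            sorted(row_lookup[g] for g in mt.members), dtype=np.intp
        )
        mapped.append((gs.name, idx))
    if not mapped:
        raise ValueError("no tag survives universe intersection")

    if weight_exponent == 0.0:
        ranks = _rank_position_matrix(expr.values, axis=0)  # (n, m)
        rows = np.empty((len(mapped), m))
        for i, (_, idx) in enumerate(mapped):
            rows[i] = ks_from_position_matrix(ranks[idx, :], n, axis=0)
    else:
        rows = np.empty((len(mapped), m))
        for c, col_id in enumerate(expr.col_ids):
            rp = rank_profile(expr.col(col_id))
            for i, (name, idx) in enumerate(mapped):
                members = [expr.row_ids[k] for k in idx]
                rows[i, c] = ks_enrichment_score(rp, members, weight_exponent)

    matrix = ExpressionMatrix(
        row_ids=tuple(name for name, _ in mapped),
        col_ids=expr.col_ids,
        values=rows,
        value_kind="es",
    )
    return TagEsBuild(matrix=matrix, exclusions=exclusions)


def average_by_drug(
    expr: ExpressionMatrix, annotation: InstanceAnnotation
) -> ExpressionMatrix:
    """Collapse instance columns to drug columns by the arithmetic mean.

    Drug order follows first appearance among ``expr``'s columns.  Every
    column must be annotated.
    """
    groups: dict[str, list[int]] = {}
    for c, col_id in enumerate(expr.col_ids):
        try:
            drug = annotation.drug_of(col_id)
        except KeyError:
            raise KeyError(f"instance {col_id!r} missing from annotation")
        groups.setdefault(drug, []).append(c)
    drugs = tuple(groups)
    values = np.column_stack(
        [expr.values[:, groups[d]].mean(axis=1) for d in drugs]
    )
    return ExpressionMatrix(expr.row_ids, drugs, values, expr.value_kind)


def drug_level_es(
    vd: Mapping[str, float] | pd.Series,
    drug_instances: Iterable[str],
    weight_exponent: float = 0.0,
) -> float:
    """Connectivity score of a drug within one tag's per-instance score vector.

    The vector Vd (one tag's enrichment scores over all instances) is ranked
    descending and the drug's treatment instances play the role of the query
    set — the same KS kernel as the tag-level score.
    """
    rp = rank_profile(vd)
    instances = set(drug_instances)
    unknown = instances.difference(rp.ordered_ids)
    if unknown:
        raise KeyError(f"unknown instance ids: {sorted(unknown)[:5]}")
    return ks_enrichment_score(rp, instances, weight_exponent)


def drug_es_matrix(
    tag_instance_es: ExpressionMatrix,
    annotation: InstanceAnnotation,
    weight_exponent: float = 0.0,
) -> ExpressionMatrix:
    """Build the tag x drug connectivity matrix from a tag x instance matrix.

    For every tag, the instance scores (Vd) are ranked and each drug's
    instances are scored as a query set.  Drug order follows first
    appearance among the instance columns.
    """
    groups: dict[str, list[int]] = {}
    for c, col_id in enumerate(tag_instance_es.col_ids):
        try:
            drug = annotation.drug_of(col_id)
        except KeyError:
            raise KeyError(f"instance {col_id!r} missing from annotation")
        groups.setdefault(drug, []).append(c)
    drugs = tuple(groups)
    m = len(tag_instance_es.col_ids)
    if weight_exponent == 0.0:
        ranks = _rank_position_matrix(tag_instance_es.values, axis=1)
        values = np.column_stack(
            [
                ks_from_position_matrix(ranks[:, groups[d]], m, axis=1)
                for d in drugs
            ]
        )
    else:
        values = np.empty((tag_instance_es.shape[0], len(drugs)))
        for i, tag in enumerate(tag_instance_es.row_ids):
            vd = tag_instance_es.row(tag)
            for jd, d in enumerate(drugs):
                instances = [tag_instance_es.col_ids[c] for c in groups[d]]
                values[i, jd] = drug_level_es(vd, instances, weight_exponent)
    return ExpressionMatrix(tag_instance_es.row_ids, drugs, values, "es")


def top_variance_select(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k rows with the largest sample variance (n-1 denominator).

    Rows are returned in descending-variance order; ties keep the original
    row order.
    """
    n_rows = expr.shape[0]
    if not 0 < k <= n_rows:
        raise ValueError(f"k must be in [1, {n_rows}], got {k}")
    variances = expr.values.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")[:k]
    return ExpressionMatrix(
        tuple(expr.row_ids[i] for i in order),
        expr.col_ids,
        expr.values[order],
        expr.value_kind,
    )
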