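"""Permutation null models for enrichment scores.

Two nulls are used at the two levels of the analysis:

* **instance permutation** — for a tag x drug connectivity score, the drug's
  ``t`` treatment instances are replaced by ``t`` instances drawn uniformly
  without replacement from all instances; yields the normalized enrichment
  score (NES = ES0 / mean of the null) and a two-sided permutation p-value.
* **gene permutation** — for a tag scored against one expression profile,
  the tag's genes are replaced by random genes from the whole pool on the
  same ranked profile; used to cull significantly enriched tags before
  local clustering (threshold p < 0.005 by default downstream).

The two-sided p-value is the add-one permutation estimator on |ES|:
``p = (1 + #{ |null_i| >= |ES0| }) / (r + 1)``, which is never zero and is
exact under exchangeability.  Each (tag, target) pair gets its own RNG
stream derived from the master seed by stable hashing, so batch results are
independent of evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_MIN_TAG_SIZE,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SymbolMap,
    map_tag_to_universe,
)
from .enrichment import (
    EmptyIntersectionError,
    ks_from_position_matrix,
    ks_from_positions,
    rank_profile,
)

__all__ = [
    "PermutationConfig",
    "NullDistribution",
    "NearZeroNullMeanError",
    "derive_rng",
    "instance_permutation_null",
    "two_sided_p",
    "nes_from_null",
    "gene_permutation_p",
    "GenePermutationResult",
    "gene_permutation_pvalue_matrix",
]

DEFAULT_TRIALS = 10_000


@dataclass(frozen=True)
class PermutationConfig:
    """Trial count and master seed for a permutation test (two-sided)."""

    r: int = DEFAULT_TRIALS
    seed: int = 0
    epsilon: float = 1e-12  # guard for the NES null-mean denominator

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")


@dataclass(frozen=True)
class NullDistribution:
    """Randomized enrichment scores plus the observed score they test."""

    values: np.ndarray
    es0: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("null values must be a nonempty 1-D array")
        if np.abs(values).max() > 1.0 + 1e-12:
            raise ValueError("null enrichment scores must lie in [-1, 1]")

    @property
    def r(self) -> int:
        return self.values.size


class NearZeroNullMeanError(ArithmeticError):
    """NES denominator too close to zero; carries the offending mean."""

    def __init__(self, mean: float, epsilon: float):
        super().__init__(
            f"null mean {mean!r} within epsilon {epsilon!r} of zero; "
            "report ES0 instead of NES"
        )
        self.mean = mean
        self.epsilon = epsilon


def derive_rng(seed: int, *tokens: object) -> np.random.Generator:
    """A reproducible RNG stream keyed by (seed, tokens) via stable hashing."""
    keys = [seed & 0x7FFFFFFF]
    keys += [zlib.crc32(str(t).encode("utf-8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _sample_position_sets(
    rng: np.random.Generator, r: int, n: int, t: int, max_elements: int = 20_000_000
) -> np.ndarray:
    """r sets of t distinct 1-based positions, uniform over {1..n} subsets.

    Vectorized via argpartition of uniform keys, chunked to bound memory.
    """
    chunk = max(1, min(r, max_elements // max(n, 1)))
    out = np.empty((r, t), dtype=np.intp)
    start = 0
    while start < r:
        stop = min(start + chunk, r)
        keys = rng.random((stop - start, n))
        if t < n:
            out[start:stop] = np.argpartition(keys, t - 1, axis=1)[:, :t] + 1
        else:
            out[start:stop] = np.arange(1, n + 1, dtype=np.intp)
        start = stop
    return out


# ---------------------------------------------------------------------------
# instance permutation (drug-level null)
# ---------------------------------------------------------------------------


def instance_permutation_null(
    vd: Mapping[str, float] | pd.Series,
    drug_instances: Iterable[str] | int,
    cfg: PermutationConfig,
    *,
    stream: tuple[object, ...] = (),
) -> NullDistribution:
    """Null connectivity scores from random treatment groups of size ``t``.

    ``drug_instances`` may be the drug's instance-id set (the observed score
    is then computed from it) or a bare group size ``t`` (the observed score
    is recorded as NaN and only the null is built).  Each trial draws ``t``
    distinct instances uniformly without replacement and scores them with
    the same KS kernel as the observed drug.  ``stream`` tokens (e.g. the
    tag and drug names) select the reproducible per-pair RNG stream.
    """
    rp = rank_profile(vd)
    n = rp.N
    if isinstance(drug_instances, (int, np.integer)):
        t = int(drug_instances)
        es0 = float("nan")
    else:
        instances = set(drug_instances)
        unknown = instances.difference(rp.ordered_ids)
        if unknown:
            raise KeyError(f"unknown instance ids: {sorted(unknown)[:5]}")
        t = len(instances)
        es0 = (
            ks_from_positions(rp.positions(instances), n) if t < n else 0.0
        )
    if not 1 <= t <= n:
        raise ValueError(f"group size t={t} outside [1, {n}]")
    if t == n:
        # Sampling without replacement forces every trial to select all
        # instances, i.e. exactly the observed set: the null is a constant
        # equal to ES0 (the running sum of the full set has zero deviation).
        # Downstream this forces p = 1 and NES = 1 exactly.
        return NullDistribution(values=np.zeros(cfg.r), es0=0.0)
    rng = derive_rng(cfg.seed, "instance-null", t, *stream)
    positions = _sample_position_sets(rng, cfg.r, n, t)
    values = ks_from_position_matrix(positions, n, axis=1)
    return NullDistribution(values=values, es0=es0)


def two_sided_p(null: NullDistribution) -> float:
    """Add-one two-sided permutation p-value of the observed score."""
    if not np.isfinite(null.es0):
        raise ValueError("null distribution has no observed score")
    count = int(np.count_nonzero(np.abs(null.values) >= abs(null.es0)))
    return (1 + count) / (null.r + 1)


def nes_from_null(null: NullDistribution, epsilon: float = 1e-12) -> float:
    """Normalized enrichment score: ES0 divided by the raw null mean.

    Raises :class:`NearZeroNullMeanError` when the null mean is within
    ``epsilon`` of zero so callers can fall back to reporting ES0 — the
    policy is surfaced, not hidden.
    """
    if not np.isfinite(null.es0):
        raise ValueError("null distribution has no observed score")
    if np.all(null.values == null.es0):
        # Degenerate null (e.g. t = all instances): every trial reproduces
        # the observed selection, so the normalized score is 1 by the
        # constant-null limit of ES0 / mean.
        return 1.0
    mean = float(null.values.mean())
    if abs(mean) <= epsilon:
        raise NearZeroNullMeanError(mean, epsilon)
    return float(null.es0) / mean


# ---------------------------------------------------------------------------
# gene permutation (tag-culling null)
# ---------------------------------------------------------------------------


def gene_permutation_p(
    profile: Mapping[str, float] | pd.Series,
    tag: GeneSet | Iterable[str],
    cfg: PermutationConfig,
    *,
    min_tag_size: int = DEFAULT_MIN_TAG_SIZE,
    stream: tuple[object, ...] = (),
) -> float:
    """Two-sided gene-permutation p for one tag on one expression profile.

    Each trial replaces the tag's genes by a random same-size draw from the
    whole gene pool and rescores on the same ranked profile.
    """
    rp = rank_profile(profile)
    members = set(tag.members) if isinstance(tag, GeneSet) else set(tag)
    pos = rp.positions(members)
    s = pos.shape[0]
    if s == 0:
        raise EmptyIntersectionError(
            "tag has no members in the profile's universe"
        )
    if s < min_tag_size:
        raise ValueError(f"mapped tag size {s} < min_tag_size {min_tag_size}")
    if s >= rp.N:
        raise ValueError("tag size must be smaller than the gene pool")
    es0 = ks_from_positions(pos, rp.N)
    name = tag.name if isinstance(tag, GeneSet) else ""
    rng = derive_rng(cfg.seed, "gene-null", name, *stream)
    positions = _sample_position_sets(rng, cfg.r, rp.N, s)
    values = ks_from_position_matrix(positions, rp.N, axis=1)
    return two_sided_p(NullDistribution(values=values, es0=es0))


@dataclass(frozen=True)
class GenePermutationResult:
    """Batch gene-permutation output: tag x target ES and p matrices."""

    es: ExpressionMatrix
    p_values: ExpressionMatrix
    exclusions: dict[str, str]


def gene_permutation_pvalue_matrix(
    expr: ExpressionMatrix,
    tags: GeneSetCollection,
    cfg: PermutationConfig,
    symbol_map: SymbolMap | None = None,
    *,
    min_tag_size: int = DEFAULT_MIN_TAG_SIZE,
) -> GenePermutationResult:
    """Gene-permutation ES and p for every tag against every column of ``expr``.

    The w=0 KS score depends on member *positions* only, and under gene
    permutation those positions are a uniform size-s subset of {1..N} for
    every column; the null distribution therefore depends only on the mapped
    set size, and one shared null per distinct size (its own seeded stream)
    gives exactly the same marginal law as per-pair sampling.  p-values are
    read off by binary search against the sorted |null|.
    """
    n, m = expr.shape
    row_lookup = {r: i for i, r in enumerate(expr.row_ids)}
    mapped: list[tuple[str, np.ndarray]] = []
    exclusions: dict[str, str] = {}
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

    from .enrichment import _rank_position_matrix  # shared ranking kernel

    ranks = _rank_position_matrix(expr.values, axis=0)
    es = np.empty((len(mapped), m))
    for i, (_, idx) in enumerate(mapped):
        es[i] = ks_from_position_matrix(ranks[idx, :], n, axis=0)

    sizes = sorted({idx.shape[0] for _, idx in mapped})
    null_abs_sorted: dict[int, np.ndarray] = {}
    for s in sizes:
        rng = derive_rng(cfg.seed, "gene-null-size", s, n)
        positions = _sample_position_sets(rng, cfg.r, n, s)
        null = ks_from_position_matrix(positions, n, axis=1)
        null_abs_sorted[s] = np.sort(np.abs(null))

    p = np.empty_like(es)
    for i, (_, idx) in enumerate(mapped):
        sorted_abs = null_abs_sorted[idx.shape[0]]
        # count of |null| >= |es| via left bisection on the sorted |null|
        count = cfg.r - np.searchsorted(sorted_abs, np.abs(es[i]), side="left")
        p[i] = (1 + count) / (cfg.r + 1)

    tag_names = tuple(name for name, _ in mapped)
    return GenePermutationResult(
        es=ExpressionMatrix(tag_names, expr.col_ids, es, "es"),
        p_values=ExpressionMatrix(tag_names, expr.col_ids, p, "log_ratio"),
        exclusions=exclusions,
    )
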