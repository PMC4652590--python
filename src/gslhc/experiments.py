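"""Reproducible study-condition experiments on synthetic fixtures.

These functions wire the package's pieces into the headline experiments:
permutation-test calibration, recovery of planted drug groups by the local
clustering protocol, the cell-type-dominance contrast between gene-space
and tag-space clustering, and the same-group correlation comparison between
the two feature spaces.  They are used both by the test suite and by the
acceptance script; all randomness is controlled by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import average_linkage, pearson_distance
from .enrichment import (
    average_by_drug,
    drug_es_matrix,
    tag_instance_es_matrix,
    top_variance_select,
)
from .evaluation import dendrogram_fscore, group_correlation_compare
from .permutation import (
    PermutationConfig,
    derive_rng,
    gene_permutation_p,
    gene_permutation_pvalue_matrix,
    instance_permutation_null,
    two_sided_p,
)
from .pipeline import GslhcQuery, gslhc_run
from .synthetic import SimulationConfig, generate_fixture

__all__ = [
    "CalibrationResult",
    "type_i_calibration",
    "RecoveryResult",
    "planted_recovery",
    "DominanceResult",
    "cell_type_dominance",
    "CorrelationGapResult",
    "same_group_correlation_gap",
]


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    """Empirical type-I rates of a permutation test under a simulated null."""

    p_values: np.ndarray
    rates: dict[float, float]  # nominal alpha -> empirical rejection rate

    def binomial_se(self, alpha: float) -> float:
        return float(np.sqrt(alpha * (1 - alpha) / self.p_values.size))


def type_i_calibration(
    null_model: str,
    n_cases: int = 2000,
    r: int = 500,
    seed: int = 0,
    alphas: Sequence[float] = (0.05, 0.01),
    n_items: int = 100,
    set_size: int = 5,
) -> CalibrationResult:
    """Empirical rejection rates when the null hypothesis is true.

    ``null_model='instance'`` simulates an exchangeable per-instance score
    vector and a random treatment group tested by instance permutation;
    ``null_model='gene'`` simulates an exchangeable expression profile and
    a random tag tested by gene permutation.  Rejection uses ``p <= alpha``.
    """
    if null_model not in ("instance", "gene"):
        raise ValueError("null_model must be 'instance' or 'gene'")
    ids = [f"x{i:04d}" for i in range(n_items)]
    p_values = np.empty(n_cases)
    for case in range(n_cases):
        rng = derive_rng(seed, "calibration", null_model, case)
        values = pd.Series(rng.normal(size=n_items), index=ids)
        picked = [ids[k] for k in rng.choice(n_items, set_size, replace=False)]
        cfg = PermutationConfig(r=r, seed=int(rng.integers(2**31 - 1)))
        if null_model == "instance":
            null = instance_permutation_null(values, set(picked), cfg)
            p_values[case] = two_sided_p(null)
        else:
            p_values[case] = gene_permutation_p(
                values, set(picked), cfg, min_tag_size=min(set_size, 10)
            )
    rates = {a: float(np.mean(p_values <= a)) for a in alphas}
    return CalibrationResult(p_values=p_values, rates=rates)


# ---------------------------------------------------------------------------
# planted-structure recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryResult:
    seeds: tuple[int, ...]
    jaccards: np.ndarray  # one per seed: recovered vs expected partner drugs
    n_culled: tuple[int, ...]

    @property
    def mean_jaccard(self) -> float:
        return float(self.jaccards.mean())


def planted_recovery(
    seeds: Sequence[int],
    cfg: SimulationConfig = SimulationConfig(),
    r: int = 2000,
) -> RecoveryResult:
    """Query two members of a planted drug group; score partner recovery.

    For each seed a fixture is generated, tag x drug enrichment scores and
    gene-permutation p-values are computed on the drug-averaged profiles,
    and the protocol is run with two group members as the query.  The
    Jaccard index compares the reported partner drugs with the remaining
    group members.
    """
    jaccards = []
    n_culled = []
    for seed in seeds:
        bundle = generate_fixture(replace(cfg, seed=seed))
        drug_profiles = average_by_drug(bundle.expression, bundle.annotation)
        result = gene_permutation_pvalue_matrix(
            drug_profiles,
            bundle.tags,
            PermutationConfig(r=r, seed=seed),
        )
        groups = sorted(set(bundle.truth.drug_group.values()))
        group = groups[seed % len(groups)]
        members = sorted(bundle.truth.group_members(group))
        query = GslhcQuery(query_drugs=frozenset(members[:2]))
        report = gslhc_run(result.es, result.p_values, query)
        expected = set(members[2:])
        got = set(report.partner_drugs)
        union = expected | got
        jaccards.append(len(expected & got) / len(union) if union else 1.0)
        n_culled.append(len(report.culled_tags))
    return RecoveryResult(
        seeds=tuple(seeds),
        jaccards=np.asarray(jaccards),
        n_culled=tuple(n_culled),
    )


# ---------------------------------------------------------------------------
# cell-type dominance contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DominanceResult:
    seeds: tuple[int, ...]
    gene_space_cell_f: np.ndarray
    tag_space_cell_f: np.ndarray
    tag_space_group_f: np.ndarray


def cell_type_dominance(
    seeds: Sequence[int],
    cfg: SimulationConfig = SimulationConfig(),
    top_k: int = 300,
) -> DominanceResult:
    """Instance clustering judged as a cell-line classifier in two spaces.

    Gene space: the top ``top_k`` highest-variance genes of the log-ratio
    matrix.  Tag space: the tag x instance enrichment-score matrix (top
    ``top_k`` highest-variance tags when more are available).  Both are
    clustered by Pearson distance + average linkage and scored with the
    size-weighted classification F against cell-line labels; tag space is
    additionally scored against planted drug-group labels.
    """
    gene_f, tag_f, group_f = [], [], []
    for seed in seeds:
        bundle = generate_fixture(replace(cfg, seed=seed))
        expr = bundle.expression
        cell_labels = {
            inst: bundle.truth.instance_cell_line[inst] for inst in expr.col_ids
        }
        group_labels = {
            inst: bundle.truth.drug_group[bundle.truth.instance_drug[inst]]
            for inst in expr.col_ids
        }

        gene_sub = top_variance_select(expr, min(top_k, expr.shape[0]))
        gene_tree = average_linkage(pearson_distance(gene_sub, axis="columns"))
        gene_f.append(dendrogram_fscore(gene_tree, cell_labels).weighted_f)

        es = tag_instance_es_matrix(expr, bundle.tags).matrix
        es_sub = top_variance_select(es, min(top_k, es.shape[0]))
        tag_tree = average_linkage(pearson_distance(es_sub, axis="columns"))
        tag_f.append(dendrogram_fscore(tag_tree, cell_labels).weighted_f)
        group_f.append(dendrogram_fscore(tag_tree, group_labels).weighted_f)
    return DominanceResult(
        seeds=tuple(seeds),
        gene_space_cell_f=np.asarray(gene_f),
        tag_space_cell_f=np.asarray(tag_f),
        tag_space_group_f=np.asarray(group_f),
    )


# ---------------------------------------------------------------------------
# same-group correlation comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationGapResult:
    seeds: tuple[int, ...]
    tag_space_mean: np.ndarray  # per seed: mean same-group r in tag space
    gene_space_mean: np.ndarray

    @property
    def mean_gap(self) -> float:
        return float((self.tag_space_mean - self.gene_space_mean).mean())


def same_group_correlation_gap(
    seeds: Sequence[int],
    cfg: SimulationConfig = SimulationConfig(),
) -> CorrelationGapResult:
    """Same-group drug-pair correlations: tag space vs gene space.

    Tag space is each drug's functional profile — the enrichment scores of
    all tags on the drug-averaged log-ratio profile (the same object the
    local-clustering pipeline works on); gene space is the drug-averaged
    log-ratio matrix restricted to its top highest-variance genes (as many
    as there are tags).
    """
    tag_means, gene_means = [], []
    for seed in seeds:
        bundle = generate_fixture(replace(cfg, seed=seed))
        consensus = average_by_drug(bundle.expression, bundle.annotation)
        tag_drug = tag_instance_es_matrix(consensus, bundle.tags).matrix
        gene_drug = top_variance_select(
            consensus, min(tag_drug.shape[0], consensus.shape[0])
        )
        pairs = []
        for group in sorted(set(bundle.truth.drug_group.values())):
            members = sorted(bundle.truth.group_members(group))
            pairs.extend(
                (members[i], members[j])
                for i in range(len(members))
                for j in range(i + 1, len(members))
            )
        res = group_correlation_compare(tag_drug, gene_drug, pairs)
        tag_means.append(res.mean_a)
        gene_means.append(res.mean_b)
    return CorrelationGapResult(
        seeds=tuple(seeds),
        tag_space_mean=np.asarray(tag_means),
        gene_space_mean=np.asarray(gene_means),
    )
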