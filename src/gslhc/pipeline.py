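"""The local hierarchical clustering protocol over gene-set profiles.

Given a tag x drug enrichment-score matrix and matching gene-permutation
p-values, the protocol (i) takes a query drug set, (ii) culls the tags
significantly enriched against *every* query drug (p below a threshold,
default 0.005), (iii) two-way clusters the culled tags against all drugs
and cuts out the drug clade containing the query with cophenetic
correlation above a threshold (default 0.9).  Drugs in that clade beyond
the query are reported as partner drugs; the tag dendrogram is kept for
functional interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .clustering import Clade, extract_clade, two_way_cluster
from .core_io import Dendrogram, ExpressionMatrix

__all__ = ["GslhcQuery", "GslhcReport", "cull_tags", "gslhc_run"]


@dataclass(frozen=True)
class GslhcQuery:
    """A query drug set with culling and clade thresholds."""

    query_drugs: frozenset[str]
    p_threshold: float = 0.005
    corr_threshold: float = 0.9

    def __post_init__(self) -> None:
        drugs = frozenset(str(d) for d in self.query_drugs)
        if not drugs:
            raise ValueError("query drug set must be nonempty")
        object.__setattr__(self, "query_drugs", drugs)
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class GslhcReport:
    """Outcome of one protocol run.

    ``culled_tags`` maps each retained tag to its per-query-drug p-values;
    ``partner_drugs`` are the clade members beyond the query (empty with
    ``clade.qualifying`` False when no threshold-satisfying clade exists).
    """

    query: GslhcQuery
    culled_tags: dict[str, dict[str, float]]
    clade: Clade
    partner_drugs: tuple[str, ...]
    tag_dendrogram: Dendrogram | None
    drug_dendrogram: Dendrogram | None
    reordered: ExpressionMatrix | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "query_drugs": sorted(self.query.query_drugs),
            "p_threshold": self.query.p_threshold,
            "corr_threshold": self.query.corr_threshold,
            "culled_tags": self.culled_tags,
            "clade_members": sorted(self.clade.members),
            "clade_max_internal_height": self.clade.max_internal_height,
            "clade_qualifying": self.clade.qualifying,
            "partner_drugs": list(self.partner_drugs),
            "provenance": self.provenance,
        }


def _check_inputs(
    es_matrix: ExpressionMatrix,
    pvals: ExpressionMatrix,
    query: GslhcQuery,
) -> None:
    if es_matrix.row_ids != pvals.row_ids or es_matrix.col_ids != pvals.col_ids:
        raise ValueError("ES and p-value matrices must share both axes")
    missing = [d for d in sorted(query.query_drugs) if d not in es_matrix.col_ids]
    if missing:
        raise KeyError(f"query drugs absent from the matrix: {missing[:5]}")


def cull_tags(
    es_matrix: ExpressionMatrix,
    pvals: ExpressionMatrix,
    query: GslhcQuery,
) -> list[str]:
    """Tags with p < p_threshold for every query drug, original order kept."""
    _check_inputs(es_matrix, pvals, query)
    cols = [pvals.col_index(d) for d in sorted(query.query_drugs)]
    keep = (pvals.values[:, cols] < query.p_threshold).all(axis=1)
    return [tag for tag, k in zip(pvals.row_ids, keep) if k]


def gslhc_run(
    es_matrix: ExpressionMatrix,
    pvals: ExpressionMatrix,
    query: GslhcQuery,
    provenance: Mapping | None = None,
) -> GslhcReport:
    """Run the full protocol: cull, two-way cluster, cut the query clade.

    The culled-tag submatrix is clustered against *all* drug columns, not
    only the query.  Fewer than two culled tags leaves the drug correlation
    undefined, which is reported as a no-clade outcome rather than an error.
    """
    _check_inputs(es_matrix, pvals, query)
    culled = cull_tags(es_matrix, pvals, query)
    culled_tags = {
        tag: {
            d: float(pvals.values[pvals.row_index(tag), pvals.col_index(d)])
            for d in sorted(query.query_drugs)
        }
        for tag in culled
    }
    base_provenance = dict(provenance or {})
    base_provenance.setdefault("n_culled_tags", len(culled))
    if len(culled) < 2:
        return GslhcReport(
            query=query,
            culled_tags=culled_tags,
            clade=Clade(
                members=frozenset(query.query_drugs),
                max_internal_height=float("nan"),
                qualifying=False,
            ),
            partner_drugs=(),
            tag_dendrogram=None,
            drug_dendrogram=None,
            reordered=None,
            provenance=base_provenance,
        )
    sub = es_matrix.subset_rows(culled)
    tag_tree, drug_tree, reordered = two_way_cluster(sub)
    clade = extract_clade(drug_tree, query.query_drugs, query.corr_threshold)
    partners = tuple(
        sorted(clade.members - query.query_drugs)
    ) if clade.qualifying else ()
    return GslhcReport(
        query=query,
        culled_tags=culled_tags,
        clade=clade,
        partner_drugs=partners,
        tag_dendrogram=tag_tree,
        drug_dendrogram=drug_tree,
        reordered=reordered,
        provenance=base_provenance,
    )
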