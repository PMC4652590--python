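# gslhc — gene-set functional profiling and local clustering of drug treatments

Expression compendia such as the Connectivity Map record, for thousands of
drug treatments ("instances": one compound applied to one cell line, paired
with its untreated control), the genome-wide log-ratios of expression
against control.  Comparing treatments gene-by-gene is fragile: top
differentially-expressed genes barely reproduce between replicates, and
clustering of raw profiles is dominated by cell type rather than by drug
action.  This package implements the gene-set alternative: every profile is
converted into a vector of **enrichment scores** over a collection of named
functional gene sets ("tags"), and drugs are compared, clustered and linked
in that functional space.

## The statistic

For one instance, genes are ranked by descending log-ratio.  A tag with
members at positions `V(1) < … < V(t)` in a ranking of `N` genes gets the
two-sided Kolmogorov–Smirnov running-sum score

    a = max_j ( j/t − V(j)/N ),   b = max_j ( V(j)/N − (j−1)/t ),
    ES = a  if a ≥ b  else −b,          ES ∈ [−1, 1],

positive when the tag's genes concentrate among up-regulated genes,
negative when they concentrate among down-regulated ones.  (A GSEA-style
weighted running sum is available via `weight_exponent > 0`.)

The same kernel is applied twice:

1. **tag × instance** — each tag scored against each instance's ranked
   log-ratios (the functional profile of the treatment);
2. **tag × drug** — each tag's per-instance score vector *Vd* is ranked and
   a drug's treatment instances are scored as the query set, giving a
   drug-level connectivity score.

Significance comes from two permutation nulls: an **instance-permutation**
null (random treatment groups of the same size; yields a two-sided p and
the normalized score NES = ES₀ / mean of the null) and a
**gene-permutation** null (random same-size gene sets on the same ranked
profile; used for tag culling).  The two-sided p is the add-one estimator
`p = (1 + #{|ES_null| ≥ |ES₀|}) / (r + 1)` with `r = 10,000` trials by
default.

## The local clustering protocol

Given a query drug set (one drug of unknown action, or several drugs with
a known shared property):

1. cull the tags with gene-permutation `p < 0.005` against **every** query
   drug;
2. two-way cluster (Pearson distance `d = 1 − r`, unweighted average
   linkage) the culled tags against **all** drugs;
3. cut out the drug clade containing the query whose internal merges all
   lie at correlation ≥ 0.9; the other clade members are the reported
   partner drugs, and the tag dendrogram documents the shared functions.

Dendrograms are evaluated as classifiers with the best-node F-score: for a
class, F is the maximum over all tree nodes of the harmonic mean of
precision and recall when that node's leaves are the predicted class;
classification F is the class-size-weighted mean, with label-permutation
p-values.

## Worked example

The package ships a synthetic-compendium generator with planted structure:
drugs belong to groups sharing target tags, cell lines add tag-incoherent
main effects, and gene-level effect sizes are heterogeneous per drug (see
`docs/methods.md`).  Querying two members of a planted group:

```
$ gslhc simulate --out fix --seed 11
$ gslhc gslhc --es fix/expression.tsv --gmt fix/tags.gmt \
        --annotation fix/annotation.tsv --query D01,D06 \
        --r 2000 --seed 11 --out report.json --newick-prefix trees
averaged instances into 40 drug profiles
scored 150 tags against 40 targets (r=2000)
culled 8 tags; clade found; 7 partner drugs
```

`report.json` then contains

```
culled tags:      T001 … T008          # exactly group G1's 8 target tags
clade qualifying: true
partner drugs:    D11 D16 D21 D26 D31 D35 D36
```

The query drugs D01 and D06 belong to planted group G1 = {D01, D06, D11,
D16, D21, D26, D31, D36}; the protocol recovers all six remaining members
(plus one extra candidate, D35 — clades are candidate lists, not proofs).
Evaluating the drug dendrogram against the planted group labels:

```
$ gslhc fscore --newick trees.drugs.nwk --labels labels.tsv --out fsc.json
weighted F = 0.646 over 5 classes     # G1: F = 1.00, p = 0.01
```

G1 is perfectly resolved (its tags were the clustering features); the other
groups, whose tags were culled away, are not — which is the point of
*local* clustering.

Library use mirrors the CLI: `synthetic.generate_fixture`,
`enrichment.tag_instance_es_matrix` / `drug_es_matrix`,
`permutation.gene_permutation_pvalue_matrix`, `pipeline.gslhc_run`,
`evaluation.dendrogram_fscore`.

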