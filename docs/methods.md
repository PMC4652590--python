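# Methods

This note records the package's model choices, defaults, numerical
conventions, and what the synthetic experiments do and do not establish.

## Enrichment scores

**Ranking.** Features are ordered by descending score; ties keep input
order (stable sort), so results are deterministic and independent of hash
order.  Descending means a positive enrichment score points toward
up-regulation; the convention is fixed package-wide.

**Kernel.** The default (`weight_exponent = 0`) is the classic two-sided
KS statistic on rank positions: the upward deviation `a` is read just
after each hit, the downward deviation `b` just before one, and the signed
score is `a` if `a ≥ b` else `−b`.  Two discrete-grid consequences are
worth knowing: (i) the score of a set occupying the top `t` ranks is
exactly `1 − t/N`; (ii) reversing the ranking swaps the deviations only up
to a `1/N` boundary term (`a′ = b − 1/N`, `b′ = a + 1/N`), so the score
negates to within `1/N` except at a/b near-ties — the test suite asserts
this exact relation rather than naive anti-symmetry.  `weight_exponent =
w > 0` switches to the GSEA-style weighted running sum (hit increments
`|score|^w` normalized by their sum, miss decrement `1/(N − t)`, score =
maximum-magnitude deviation); when all hit weights are exactly zero the
increments fall back to `1/t`.

**Tag mapping.** Gene-set members are translated to platform identifiers
by exact, case-sensitive string matching (silent case-folding hides data
errors), the union of mapped identifiers is intersected with the matrix's
row universe, and tags below `min_tag_size = 10` after intersection are
dropped with a per-tag reason in the build report rather than failing the
build.  Ten is a floor against degenerate KS statistics on tiny sets; it
is configurable.  Probe-level duplicates of a symbol are all retained.

**Drug level.** A drug's connectivity score for a tag ranks the tag's
per-instance score vector (Vd) descending and scores the drug's instances
as the query set — the identical kernel, so one implementation serves both
levels.  Drug-averaged profiles use the arithmetic mean over the drug's
instances.  Top-variance selection uses the unbiased (n − 1) sample
variance, descending, ties by original row order.

## Permutation nulls

* Two-sided p is the add-one estimator on |ES|:
  `p = (1 + #{|ES_null| ≥ |ES₀|})/(r + 1)`.  It is never zero, exact under
  exchangeability, and slightly conservative.  Default `r = 10,000`
  (resolution 10⁻⁴, ample for the 0.005 culling threshold); experiments in
  this repository scale `r` down (500 for calibration, 2,000 in the
  pipeline runs) as stated per experiment.
* Instance permutation draws `t` distinct instances uniformly without
  replacement.  With `t` equal to all instances every trial reproduces the
  observed selection; the null is a constant equal to ES₀ and the code
  returns `p = 1` and `NES = 1` exactly (the constant-null limit of
  ES₀/mean).
* NES divides ES₀ by the raw (signed) null mean.  A null mean within
  `epsilon = 1e−12` of zero raises an error carrying the mean so callers
  can fall back to reporting ES₀; the signed-mean convention of GSEA is
  deliberately not silently substituted.
* Each (tag, target) pair derives its own RNG stream from the master seed
  by CRC-32 hashing of the pair's names, so batch results are independent
  of evaluation order and bit-reproducible.
* The batch gene-permutation builder shares one null distribution per
  distinct mapped set size: the w = 0 score depends only on member
  positions, and under gene permutation positions are a uniform size-s
  subset of {1..N} for every column, so the shared null has exactly the
  marginal law of per-pair sampling.  Same-size tags therefore share a
  null sample (their p-values are dependent across tags, but each is
  marginally exact); the per-pair `gene_permutation_p` keeps fully
  independent streams.

Calibration: both nulls hold their nominal type-I rates (α = 0.05 and
0.01) within three binomial standard errors over 2,000 simulated null
cases at r = 500; `scripts/acceptance.py` recomputes this.

## Clustering and clades

Distances are `d = 1 − r` (Pearson), not `1 − |r|`: anticorrelated drugs
must not cluster.  Linkage is UPGMA (unweighted average), implemented
in-package because the contract fixes deterministic tie-breaking — among
equally close pairs, the pair whose lexicographically smallest member id
sorts first merges first — which library implementations do not guarantee;
scipy's average linkage serves as an independent cross-check in the tests
(agreement to 1e−9 on tie-free matrices).  UPGMA heights are monotone
non-decreasing (each new inter-cluster distance is a mean of distances no
smaller than the current minimum), and the builder validates this.

Zero-variance items are an error listing the offending ids, not a silent
drop: in an enrichment-score matrix a constant row or column signals a
degenerate build.  The one sanctioned degeneracy: in two-way clustering,
when one axis has a single item the other axis's profiles are scalars, and
those items are joined in a flat zero-height tree (all indistinguishable)
rather than erroring.

A clade at correlation threshold `c` (default 0.9) is the **maximal**
subtree that contains every query leaf and whose internal merges all lie
at height ≤ 1 − c.  The threshold is read on cophenetic (merge-height)
correlation, not minimum pairwise leaf correlation — under the ultrametric
the condition reduces to the height of the subtree root, and the maximal
qualifying subtree is found by ascending from the queries' lowest common
ancestor.  If even the LCA violates the bound, the query ids are returned
alone with a no-clade flag.  Because the clade is maximal, reported
partner lists are supersets of any smaller qualifying clade.

## F-score evaluation

Every node of the dendrogram — leaves included — is tried as the predicted
positive set for every class; per class the maximum `2PR/(P + R)` is kept
(ties resolve to the smallest node id) and the classification score is the
class-size-weighted mean of the per-class maxima (the Larsen–Aone cluster
F-measure).  `F_i = 1` exactly when some node's leaf set equals the
class's leaf set.  Label-permutation p-values shuffle the label vector
jointly across leaves (default 100 permutations, add-one estimator).  The
best-node F statistic is heavily tied, so these p-values are conservative
(valid but super-uniform under the null) — the tests check validity, not
uniformity.  Note a structural floor: with k balanced classes the root
node alone yields `F = 2/(1 + k)` for every class, so weighted F below 0.5
is only possible with four or more balanced classes.

Top-k overlap ranks by |log-ratio| descending by default (differential
expression regardless of direction; signed ranking is an option) over the
shared feature universe.  For independent profiles the expected overlap is
k/N (≈ 0.045 at N = 22,283, k = 1,000).  The same-target comparison
reports per-pair Pearson correlations in two matrices with means, SDs, and
a Welch (unequal-variance) two-sample t; Fisher-z pooling was considered
and rejected as the summary the surrounding literature prints is the raw
mean/SD.

## The synthetic compendium

`synthetic.generate_fixture` draws, per instance,

    x(g, i) = A(g)·z(g, cell(i)) + δ·s(g, d)·L(g, d) + ε(g, i)

with `z ~ N(0, cell_effect_sd²)` per (gene, cell line), `A(g)` lognormal
(sdlog `cell_marker_dispersion`), `s(g, d) ∈ {−1, 0, +1}` the signed
target pattern (member genes of the drug's target tags; half of each
group's tags are repressed), `L(g, d)` lognormal (sdlog
`drug_effect_dispersion`) and `ε ~ N(0, noise_sd²)`.  Cell lines are
assigned to instances uniformly at random.

Each mechanism emulates a documented property of real treatment compendia,
and each is what makes the corresponding headline result possible — made
explicit here so the claims are falsifiable in-code:

* **Marker-tailed cell effects** (`A(g)`): a minority of genes carries
  most between-cell-line variance, so top-variance selection concentrates
  cell signal and gene-space instance clustering is cell-dominated.
* **Tag-incoherent cell effects**: `z` is independent of tag membership,
  so cell lines perturb tag scores only through a bounded rank-statistic
  fingerprint (≈ 1/√s), while instance noise comparable to typical cell
  effects keeps that fingerprint unstable — tag-space clustering is then
  drug-group-, not cell-, dominated.
* **Heterogeneous effect magnitudes** (`L(g, d)`): same-group drugs share
  which functions they act on but not gene-level effect sizes — the
  gene-level irreproducibility seen in real replicates.  Magnitude-weighted
  gene-space correlation suffers; the rank-based enrichment score, which
  only needs member genes to move coherently, does not.  This is the
  mechanism behind the same-group correlation gap.
* **Random cell-line composition**: different drugs are profiled in
  different cell mixes, contaminating gene-space drug profiles with
  cell signal that enrichment profiles suppress.

Defaults (chosen once as the package's study conditions): 2,000 genes,
150 tags of 20–80 genes, 40 drugs in 5 groups of 8 sharing 8 target tags,
4 instances per drug, **4 cell lines** (the balanced-class F-score floor
`2/(1 + k)` makes a cell-line F below 0.5 unattainable with 3 balanced
cell lines; four matches the compendium this emulates),
`cell_effect_sd = 1`, `cell_marker_dispersion = 1.25`,
`drug_effect_size = 4` (median shift, ≈ 2.7× the noise SD),
`drug_effect_dispersion = 1`, `noise_sd = 1.5`.  The full pipeline on a
default fixture runs in a few seconds; ten-seed experiment batteries run
in well under a minute.

What the synthetic results do **not** show: the generator has no batch or
platform effects, no dose–response structure, no tag-tag correlation
beyond random membership overlap, and its cell effects are additive and
time-invariant.  Passing the planted-recovery and dominance tests
demonstrates that the implementation realizes the method's mechanics under
the assumed generative model, not that the model matches any particular
real compendium; the real-data reproduction test (skipped unless the
published supplementary matrices are downloaded) covers the latter.

## Pipeline conventions

The culling p-values and the clustered enrichment matrix are computed at
the **one-level** tag × drug stage: tags scored against each drug's
averaged log-ratio profile, matching the gene-permutation null, which
rescores random gene sets on a single ranked profile.  The two-level
connectivity score (rank Vd, query the drug's instances) is what the
`drug-es` CLI command and `enrichment.drug_es_matrix` produce, with NES
and instance-permutation p per (tag, drug); with only a handful of
instances per drug it is coarse-grained (its value grid has resolution
~1/t), which is why the clustering stage prefers the one-level profiles.
Clustering uses ES values; NES is available by configuration.  A query of
a single unknown compound is the same code path as a multi-drug query.
Fewer than two culled tags makes drug correlation undefined and is
reported as a no-clade outcome, not an error.  No multiplicity correction
is applied across tags: the protocol thresholds raw permutation p-values
at 0.005 by design.

## Problem sizes in the shipped experiments

Calibration uses 2,000 null cases × 500 trials; recovery, dominance and
correlation experiments use ten fixtures at the default scale with
r = 2,000 for culling p-values.  These sizes give sub-minute batteries
while leaving the binomial error bands far narrower than the effects being
checked.
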