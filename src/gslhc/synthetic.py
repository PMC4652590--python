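"""Synthetic treatment-profile fixtures with planted functional structure.

The generator emulates the statistical skeleton of a drug-treatment
log-ratio compendium: every instance (one drug treatment in one cell line)
is a gene vector

    x(g, i) = alpha(g, cell(i)) + effect(g, drug(i)) + eps(g, i)

with three mechanisms copied from real treatment compendia:

* **cell-line main effects** alpha(g, c) = A(g) * z(g, c), where z is
  Gaussian per (gene, cell line) — deliberately incoherent with tag
  membership — and A(g) is a lognormal per-gene responsiveness scale: a
  minority of marker genes dominates the between-cell-line variance, the
  way cell-type markers dominate high-variance probes.
* **coherent but heterogeneous drug effects**: every member gene of a
  drug's target tags responds in a shared direction (half of each group's
  tags are repressed, mirroring that drugs both induce and repress
  pathways) but with a lognormal per-(gene, drug) magnitude — same-group
  drugs share functions, not gene-level effect sizes, reproducing the low
  reproducibility of top differentially-expressed genes.
* **instance noise** eps, Gaussian, large enough that single-gene ranks are
  unstable between replicates while the coherent tag-level shift survives.

Each instance's cell line is drawn at random, so different drugs are
profiled in different cell-line mixes — the confounder that makes
gene-space drug profiles carry cell contamination.  Drugs are organized
into groups that share target tags, giving planted drug clusters for
recovery experiments; every emitted object round-trips through the
package's text formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InstanceAnnotation,
    write_annotation,
    write_gmt,
    write_json,
    write_matrix,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "FixtureBundle",
    "generate_genesets",
    "generate_fixture",
    "emit_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and effect sizes of a synthetic compendium.

    Defaults are the package's standard study conditions: 2,000 genes,
    150 tags of 20-80 genes, 40 drugs in 5 groups of 8 sharing 4 target
    tags each (half repressed), 4 instances per drug over 4 cell lines
    assigned at random, noise_sd 1.5, unit cell-effect scale with marker
    dispersion 1.25, and a median drug effect of 4 with per-(gene, drug)
    lognormal dispersion 1.
    """

    n_genes: int = 2000
    n_tags: int = 150
    tag_size_range: tuple[int, int] = (20, 80)
    n_drugs: int = 40
    instances_per_drug: tuple[int, int] = (4, 4)
    n_cell_lines: int = 4
    n_drug_groups: int = 5
    target_tags_per_group: int = 8
    down_fraction: float = 0.5  # fraction of each group's tags repressed
    cell_effect_sd: float = 1.0
    cell_marker_dispersion: float = 1.25  # lognormal sdlog of per-gene scale
    drug_effect_size: float = 4.0  # median |log-ratio| shift of target genes
    drug_effect_dispersion: float = 1.0  # lognormal sdlog per (gene, drug)
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_tags,
            self.n_drugs,
            self.n_cell_lines,
            self.n_drug_groups,
            self.target_tags_per_group,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        lo, hi = self.tag_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid tag size range")
        if hi > self.n_genes:
            raise ValueError("tag sizes exceed the gene pool")
        lo_i, hi_i = self.instances_per_drug
        if not 1 <= lo_i <= hi_i:
            raise ValueError("invalid instances_per_drug range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.cell_effect_sd < 0 or self.drug_effect_size < 0:
            raise ValueError("effect scales must be >= 0")
        if self.cell_marker_dispersion < 0 or self.drug_effect_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ValueError("down_fraction must lie in [0, 1]")
        if self.n_drug_groups * self.target_tags_per_group > self.n_tags:
            raise ValueError("not enough tags for the requested drug groups")
        if self.n_drug_groups > self.n_drugs:
            raise ValueError("more drug groups than drugs")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a generated fixture."""

    drug_targets: dict[str, tuple[str, ...]]  # drug -> target tag names
    drug_group: dict[str, str]
    instance_drug: dict[str, str]
    instance_cell_line: dict[str, str]
    tag_members: dict[str, tuple[str, ...]]
    tag_sign: dict[str, int]  # +1 induced / -1 repressed for target tags

    def group_members(self, group: str) -> tuple[str, ...]:
        return tuple(d for d, g in self.drug_group.items() if g == group)

    def to_dict(self) -> dict:
        return {
            "drug_targets": {d: list(t) for d, t in self.drug_targets.items()},
            "drug_group": dict(self.drug_group),
            "instance_drug": dict(self.instance_drug),
            "instance_cell_line": dict(self.instance_cell_line),
            "tag_members": {t: list(m) for t, m in self.tag_members.items()},
            "tag_sign": dict(self.tag_sign),
        }


@dataclass(frozen=True)
class FixtureBundle:
    expression: ExpressionMatrix
    tags: GeneSetCollection
    annotation: InstanceAnnotation
    truth: SimulationTruth


def generate_genesets(
    n_genes: int,
    n_tags: int,
    size_range: tuple[int, int],
    seed: int,
    mode: str = "random",
    jaccard_pairs: Sequence[tuple[int, int, float]] = (),
    gene_prefix: str = "g",
    tag_prefix: str = "T",
    category: str = "SIM",
) -> GeneSetCollection:
    """Random gene-set collections with optional overlap control.

    ``mode='random'`` draws each set independently (overlap left to
    chance); ``mode='disjoint'`` partitions the pool into non-overlapping
    sets (an error when the sizes cannot fit).  ``jaccard_pairs`` plants a
    requested Jaccard overlap between designated tag index pairs by sharing
    ``m = round(J * 2s / (1 + J))`` members between two equal-size sets.
    """
    if mode not in ("random", "disjoint"):
        raise ValueError("mode must be 'random' or 'disjoint'")
    lo, hi = size_range
    if not 1 <= lo <= hi <= n_genes:
        raise ValueError("infeasible size range")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 91]))
    width = len(str(n_genes))
    genes = [f"{gene_prefix}{i:0{width}d}" for i in range(1, n_genes + 1)]
    sizes = rng.integers(lo, hi + 1, size=n_tags)
    twidth = len(str(n_tags))
    names = [f"{tag_prefix}{i:0{twidth}d}" for i in range(1, n_tags + 1)]
    members: list[set[str]] = []
    if mode == "disjoint":
        if sizes.sum() > n_genes:
            raise ValueError(
                f"disjoint sets need {sizes.sum()} genes, pool has {n_genes}"
            )
        pool = rng.permutation(n_genes)
        start = 0
        for s in sizes:
            members.append({genes[k] for k in pool[start : start + s]})
            start += s
    else:
        for s in sizes:
            idx = rng.choice(n_genes, size=int(s), replace=False)
            members.append({genes[k] for k in idx})
    for i, j, jacc in jaccard_pairs:
        if not 0.0 <= jacc <= 1.0:
            raise ValueError("requested Jaccard must lie in [0, 1]")
        s = int(sizes[i])
        shared = int(round(jacc * 2 * s / (1 + jacc)))
        base = rng.choice(n_genes, size=2 * s - shared, replace=False)
        members[i] = {genes[k] for k in base[:s]}
        members[j] = {genes[k] for k in base[s - shared :]}
    return GeneSetCollection(
        tuple(
            GeneSet(name=name, category=category, members=frozenset(m))
            for name, m in zip(names, members)
        )
    )


def generate_fixture(cfg: SimulationConfig) -> FixtureBundle:
    """Deterministically generate an expression matrix + tags + annotation + truth."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 17])
    )
    tags = generate_genesets(
        cfg.n_genes, cfg.n_tags, cfg.tag_size_range, seed=cfg.seed
    )
    width = len(str(cfg.n_genes))
    genes = tuple(f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1))
    gene_index = {g: k for k, g in enumerate(genes)}
    cells = tuple(f"CL{c + 1}" for c in range(cfg.n_cell_lines))
    dwidth = len(str(cfg.n_drugs))
    drugs = tuple(f"D{d + 1:0{dwidth}d}" for d in range(cfg.n_drugs))

    # drug groups round-robin; each group owns a distinct block of target
    # tags, half of which (down_fraction) act by repression
    groups = tuple(f"G{g + 1}" for g in range(cfg.n_drug_groups))
    drug_group = {d: groups[k % cfg.n_drug_groups] for k, d in enumerate(drugs)}
    tag_names = tags.names
    tag_sign: dict[str, int] = {}
    group_tags: dict[str, tuple[str, ...]] = {}
    tpg = cfg.target_tags_per_group
    n_down = int(round(cfg.down_fraction * tpg))
    for g, group in enumerate(groups):
        block = tag_names[g * tpg : (g + 1) * tpg]
        group_tags[group] = block
        for k, t in enumerate(block):
            tag_sign[t] = -1 if k < n_down else +1
    drug_targets = {d: group_tags[drug_group[d]] for d in drugs}

    # signed target-gene pattern per drug, then heterogeneous magnitudes
    pattern = np.zeros((cfg.n_genes, cfg.n_drugs))
    for jd, d in enumerate(drugs):
        for t in drug_targets[d]:
            idx = [gene_index[g] for g in sorted(tags[t].members)]
            pattern[idx, jd] += tag_sign[t]
    pattern = np.sign(pattern)  # overlapping-tag conflicts resolve by majority
    magnitudes = np.exp(
        rng.normal(0.0, cfg.drug_effect_dispersion, size=pattern.shape)
    )
    drug_effect = cfg.drug_effect_size * pattern * magnitudes

    # instances: per-drug replicate counts, cell lines drawn at random so
    # drugs differ in cell-line composition (the gene-space confounder)
    lo_i, hi_i = cfg.instances_per_drug
    counts = rng.integers(lo_i, hi_i + 1, size=cfg.n_drugs)
    records: list[tuple[str, str, str, str]] = []
    for jd, d in enumerate(drugs):
        for rep in range(int(counts[jd])):
            cell = cells[int(rng.integers(cfg.n_cell_lines))]
            records.append((f"{d}_r{rep + 1}", d, cell, "b1"))
    annotation = InstanceAnnotation.from_records(records)

    marker_scale = np.exp(
        rng.normal(0.0, cfg.cell_marker_dispersion, size=cfg.n_genes)
    )
    alpha = marker_scale[:, None] * rng.normal(
        0.0, cfg.cell_effect_sd, size=(cfg.n_genes, len(cells))
    )
    cell_index = {c: k for k, c in enumerate(cells)}
    drug_index = {d: k for k, d in enumerate(drugs)}
    columns = np.empty((cfg.n_genes, len(records)))
    for ci, (inst, d, cell, _) in enumerate(records):
        columns[:, ci] = (
            alpha[:, cell_index[cell]]
            + drug_effect[:, drug_index[d]]
            + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        )
    expression = ExpressionMatrix(
        row_ids=genes,
        col_ids=tuple(r[0] for r in records),
        values=columns,
        value_kind="log_ratio",
    )
    truth = SimulationTruth(
        drug_targets=drug_targets,
        drug_group=dict(drug_group),
        instance_drug={r[0]: r[1] for r in records},
        instance_cell_line={r[0]: r[2] for r in records},
        tag_members={t.name: tuple(sorted(t.members)) for t in tags},
        tag_sign=tag_sign,
    )
    return FixtureBundle(
        expression=expression, tags=tags, annotation=annotation, truth=truth
    )


def emit_fixture(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a fixture to disk in the package's text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_fixture(cfg)
    paths = {
        "expression": outdir / "expression.tsv",
        "tags": outdir / "tags.gmt",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    write_matrix(bundle.expression, paths["expression"])
    write_gmt(bundle.tags, paths["tags"])
    write_annotation(bundle.annotation, paths["annotation"])
    write_json(bundle.truth.to_dict(), paths["truth"])
    return paths
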