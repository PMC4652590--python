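"""Domain containers and text-format I/O.

All matrices follow the features-in-rows, samples-in-columns convention:
a log-ratio matrix is probes x instances, an enrichment-score matrix is
tags x instances (or tags x drugs).  Formats are plain text: GMT for gene-set
collections, TSV with a header row for matrices and annotation tables, and
Newick for dendrograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "InstanceAnnotation",
    "EnrichmentRecord",
    "Dendrogram",
    "SymbolMap",
    "MappedTag",
    "GmtParseError",
    "MatrixParseError",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "map_tag_to_universe",
    "read_newick",
    "write_newick",
]

VALUE_KINDS = ("log_ratio", "es", "nes")

#: Minimum mapped tag size after universe intersection; smaller tags are
#: flagged for exclusion because the KS statistic degenerates on tiny sets.
DEFAULT_MIN_TAG_SIZE = 10


class GmtParseError(ValueError):
    """Malformed GMT input (line number included in the message)."""


class MatrixParseError(ValueError):
    """Malformed TSV matrix input (cell location included when known)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples numeric matrix with identifiers on both axes.

    ``value_kind`` records what the numbers are: ``log_ratio`` for expression
    log-ratios, ``es`` for enrichment scores (bounded in [-1, 1]) and ``nes``
    for normalized enrichment scores (unbounded).
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray
    value_kind: str = "log_ratio"

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))
        object.__setattr__(self, "col_ids", tuple(str(c) for c in self.col_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.row_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {values.shape[0]} rows"
            )
        if len(self.col_ids) != values.shape[1]:
            raise ValueError(
                f"{len(self.col_ids)} column ids for {values.shape[1]} columns"
            )
        for axis_name, ids in (("row", self.row_ids), ("column", self.col_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if list(ids).count(i) > 1})
                raise ValueError(f"duplicate {axis_name} ids: {dupes[:5]}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {self.row_ids[bad[0]]!r}, "
                f"column {self.col_ids[bad[1]]!r}"
            )
        if self.value_kind == "es" and values.size and (
            values.min() < -1.0 - 1e-12 or values.max() > 1.0 + 1e-12
        ):
            raise ValueError("enrichment scores must lie in [-1, 1]")

    # -- convenience accessors ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self._row_lookup[row_id]
        except AttributeError:
            object.__setattr__(
                self, "_row_lookup", {r: i for i, r in enumerate(self.row_ids)}
            )
            return self._row_lookup[row_id]

    def col_index(self, col_id: str) -> int:
        try:
            return self._col_lookup[col_id]
        except AttributeError:
            object.__setattr__(
                self, "_col_lookup", {c: i for i, c in enumerate(self.col_ids)}
            )
            return self._col_lookup[col_id]

    def row(self, row_id: str) -> pd.Series:
        return pd.Series(
            self.values[self.row_index(row_id)], index=list(self.col_ids)
        )

    def col(self, col_id: str) -> pd.Series:
        return pd.Series(
            self.values[:, self.col_index(col_id)], index=list(self.row_ids)
        )

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.row_index(r) for r in row_ids]
        return ExpressionMatrix(
            tuple(row_ids), self.col_ids, self.values[idx], self.value_kind
        )

    def subset_cols(self, col_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.col_index(c) for c in col_ids]
        return ExpressionMatrix(
            self.row_ids, tuple(col_ids), self.values[:, idx], self.value_kind
        )

    def transpose(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.col_ids, self.row_ids, self.values.T, self.value_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, value_kind: str = "log_ratio"
    ) -> "ExpressionMatrix":
        return cls(
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
            value_kind,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named functional gene set ("tag") with a collection category."""

    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        members = frozenset(self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        object.__setattr__(self, "sets", sets)
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes[:5]}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        try:
            return self._by_name[name]
        except AttributeError:
            object.__setattr__(self, "_by_name", {s.name: s for s in self.sets})
            return self._by_name[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)


@dataclass(frozen=True)
class InstanceAnnotation:
    """Instance -> (drug, cell line, batch) assignments.

    An instance is one treatment record: a cell line exposed to a drug at a
    dose, paired with its untreated control.  A drug typically has several
    instances; :meth:`instances_of_drug` returns that treatment group.
    """

    table: pd.DataFrame  # columns: instance_id, drug, cell_line[, batch]

    def __post_init__(self) -> None:
        required = ["instance_id", "drug", "cell_line"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        table = self.table.copy()
        if "batch" not in table.columns:
            table["batch"] = ""
        table = table[["instance_id", "drug", "cell_line", "batch"]].astype(str)
        if table["instance_id"].duplicated().any():
            dupes = table.loc[
                table["instance_id"].duplicated(), "instance_id"
            ].tolist()
            raise ValueError(f"duplicate instance ids: {dupes[:5]}")
        object.__setattr__(self, "table", table.reset_index(drop=True))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str] | tuple[str, str, str, str]]
    ) -> "InstanceAnnotation":
        rows = [list(r) + [""] * (4 - len(r)) for r in records]
        return cls(
            pd.DataFrame(
                rows, columns=["instance_id", "drug", "cell_line", "batch"]
            )
        )

    @property
    def instance_ids(self) -> tuple[str, ...]:
        return tuple(self.table["instance_id"])

    @property
    def drugs(self) -> tuple[str, ...]:
        """Distinct drugs in first-appearance order."""
        return tuple(dict.fromkeys(self.table["drug"]))

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.table["cell_line"]))

    def drug_of(self, instance_id: str) -> str:
        return self._mapping("drug")[instance_id]

    def cell_line_of(self, instance_id: str) -> str:
        return self._mapping("cell_line")[instance_id]

    def instances_of_drug(self, drug: str) -> tuple[str, ...]:
        sub = self.table.loc[self.table["drug"] == drug, "instance_id"]
        if sub.empty:
            raise KeyError(f"unknown drug {drug!r}")
        return tuple(sub)

    def _mapping(self, column: str) -> dict[str, str]:
        attr = f"_map_{column}"
        try:
            return getattr(self, attr)
        except AttributeError:
            mapping = dict(zip(self.table["instance_id"], self.table[column]))
            object.__setattr__(self, attr, mapping)
            return mapping


@dataclass(frozen=True)
class EnrichmentRecord:
    """Observed score, normalized score and permutation p for one (tag, target)."""

    tag_name: str
    target_id: str
    es0: float
    nes: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es0 <= 1.0 + 1e-12:
            raise ValueError(f"es0 {self.es0} outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if not np.isfinite(self.nes):
            raise ValueError("nes must be finite")


@dataclass(frozen=True)
class SymbolMap:
    """Gene symbol -> platform identifier mapping (one-to-many allowed).

    Matching is exact and case-sensitive; silent case folding would hide
    data errors.  Duplicate (symbol, platform_id) pairs collapse to one.
    """

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", frozenset((str(a), str(b)) for a, b in self.pairs)
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SymbolMap":
        return cls(frozenset(pairs))

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "SymbolMap":
        return cls(frozenset((i, i) for i in ids))

    def platform_ids(self, symbol: str) -> frozenset[str]:
        try:
            mapping = self._forward
        except AttributeError:
            mapping: dict[str, set[str]] = {}
            for sym, pid in self.pairs:
                mapping.setdefault(sym, set()).add(pid)
            object.__setattr__(self, "_forward", mapping)
        return frozenset(mapping.get(symbol, ()))


@dataclass(frozen=True)
class MappedTag:
    """A tag after symbol -> platform mapping and universe intersection."""

    name: str
    members: frozenset[str]
    flagged: bool  # True when mapped size < min_tag_size (excluded downstream)


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary merge tree with heights on the d = 1 - r scale.

    Node numbering: leaves are 0..n-1 in ``leaves`` order; the k-th merge
    creates internal node n + k.  ``merges`` holds (left, right, height)
    triples; under average linkage heights are non-decreasing root-ward.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        leaves = tuple(str(x) for x in self.leaves)
        object.__setattr__(self, "leaves", leaves)
        merges = tuple(
            (int(a), int(b), float(h)) for a, b, h in self.merges
        )
        object.__setattr__(self, "merges", merges)
        n = len(leaves)
        if n == 0:
            raise ValueError("dendrogram needs at least one leaf")
        if len(set(leaves)) != n:
            raise ValueError("duplicate leaf ids")
        if len(merges) != n - 1:
            raise ValueError(
                f"{n} leaves require {n - 1} merges, got {len(merges)}"
            )
        seen: set[int] = set()
        heights = self.node_heights
        for k, (a, b, h) in enumerate(merges):
            node = n + k
            for child in (a, b):
                if not 0 <= child < node:
                    raise ValueError(f"merge {k} references invalid node {child}")
                if child in seen:
                    raise ValueError(f"node {child} merged twice")
                seen.add(child)
                if heights[child] > h + 1e-9:
                    raise ValueError(
                        "merge heights must be non-decreasing root-ward"
                    )
        # every non-root node must have been consumed by exactly one merge
        if n > 1 and len(seen) != 2 * n - 2:
            raise ValueError("tree is not a single connected binary tree")

    # -- structure ------------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_nodes(self) -> int:
        return 2 * len(self.leaves) - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def node_heights(self) -> np.ndarray:
        try:
            return self._heights
        except AttributeError:
            n = len(self.leaves)
            heights = np.zeros(2 * n - 1)
            for k, (_, _, h) in enumerate(self.merges):
                heights[n + k] = h
            object.__setattr__(self, "_heights", heights)
            return heights

    @property
    def parents(self) -> np.ndarray:
        """parent[node] (-1 for the root)."""
        try:
            return self._parents
        except AttributeError:
            n = len(self.leaves)
            parents = np.full(2 * n - 1, -1, dtype=int)
            for k, (a, b, _) in enumerate(self.merges):
                parents[a] = parents[b] = n + k
            object.__setattr__(self, "_parents", parents)
            return parents

    def leaf_indices(self, node: int) -> frozenset[int]:
        return self._leafsets()[node]

    def leaf_names(self, node: int) -> frozenset[str]:
        return frozenset(self.leaves[i] for i in self._leafsets()[node])

    def _leafsets(self) -> list[frozenset[int]]:
        try:
            return self._leafset_cache
        except AttributeError:
            n = len(self.leaves)
            sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
            for a, b, _ in self.merges:
                sets.append(sets[a] | sets[b])
            object.__setattr__(self, "_leafset_cache", sets)
            return sets

    def leaf_order(self) -> tuple[str, ...]:
        """Left-to-right leaf order of the drawn tree."""
        if self.n_leaves == 1:
            return self.leaves
        order: list[str] = []
        stack = [self.root]
        n = len(self.leaves)
        while stack:
            node = stack.pop()
            if node < n:
                order.append(self.leaves[node])
            else:
                a, b, _ = self.merges[node - n]
                stack.append(b)
                stack.append(a)
        return tuple(order)

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights between leaves (leaf order of ``leaves``)."""
        n = len(self.leaves)
        out = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            left = sorted(self._leafsets()[a])
            right = sorted(self._leafsets()[b])
            out[np.ix_(left, right)] = h
            out[np.ix_(right, left)] = h
        return out

    # -- TreeNode conversion ---------------------------------------------------

    def to_treenode(self) -> TreeNode:
        heights = self.node_heights
        n = len(self.leaves)
        nodes: list[TreeNode] = [TreeNode(name=name) for name in self.leaves]
        for k, (a, b, h) in enumerate(self.merges):
            left, right = nodes[a], nodes[b]
            left.length = h - heights[a]
            right.length = h - heights[b]
            nodes.append(TreeNode(children=[left, right]))
        return nodes[-1]

    @classmethod
    def from_treenode(cls, tree: TreeNode) -> "Dendrogram":
        """Rebuild a merge list from an ultrametric binary TreeNode."""
        tips = list(tree.tips()) if tree.children else [tree]
        leaves = tuple(t.name for t in tips)
        if len(leaves) == 1:
            return cls(leaves, ())
        index = {id(t): i for i, t in enumerate(tips)}
        heights: dict[int, float] = {}
        internal: list[TreeNode] = []

        def fill(node: TreeNode) -> float:
            if not node.children:
                heights[id(node)] = 0.0
                return 0.0
            if len(node.children) != 2:
                raise ValueError("dendrogram trees must be strictly binary")
            hs = [
                fill(child) + (child.length or 0.0) for child in node.children
            ]
            h = max(hs)  # equal up to round-off for ultrametric trees
            heights[id(node)] = h
            internal.append(node)
            return h

        fill(tree)
        internal.sort(
            key=lambda nd: (
                heights[id(nd)],
                min(index[id(t)] for t in (nd.tips() if nd.children else [nd])),
            )
        )
        node_ids = dict(index)
        merges = []
        for k, nd in enumerate(internal):
            a, b = (node_ids[id(c)] for c in nd.children)
            if a > b:
                a, b = b, a
            merges.append((a, b, heights[id(nd)]))
            node_ids[id(nd)] = len(leaves) + k
        return cls(leaves, tuple(merges))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, ``name TAB description TAB members...``.

    Duplicate member identifiers within a line collapse to one.  The
    description field is stored as the set's category (e.g. C2-C5), whatever
    its value.
    """
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, category = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise GmtParseError(f"line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, category=category, members=members))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (member order is sorted for stability)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for gs in collection:
            for label in (gs.name, gs.category):
                if "\t" in label or "\n" in label:
                    raise ValueError(
                        f"gene set field {label!r} contains a GMT delimiter"
                    )
            bad = [m for m in gs.members if "\t" in m or "\n" in m]
            if bad:
                raise ValueError(
                    f"members of {gs.name!r} contain GMT delimiters: {bad[:3]}"
                )
            fh.write("\t".join([gs.name, gs.category, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and annotation tables
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, value_kind: str = "log_ratio") -> ExpressionMatrix:
    """Read a TSV matrix: header row of column ids, first column of row ids."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n\r").split("\t")
    col_ids = header[1:]  # pandas mangles duplicate headers, so check raw
    if len(set(col_ids)) != len(col_ids):
        dupes = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise MatrixParseError(f"duplicate column ids: {dupes[:5]}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise MatrixParseError(f"duplicate row ids: {dupes[:5]}")
    for col in frame.columns:
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise MatrixParseError(
                f"non-numeric or missing value at row {bad[0]!r}, column {col!r}"
            )
        frame[col] = series
    return ExpressionMatrix.from_frame(frame, value_kind=value_kind)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="id")


def read_annotation(path: str | Path) -> InstanceAnnotation:
    """Read an instance annotation TSV with columns instance_id, drug, cell_line[, batch]."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return InstanceAnnotation(table)


def write_annotation(annotation: InstanceAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# symbol mapping
# ---------------------------------------------------------------------------


def map_tag_to_universe(
    tag: GeneSet,
    symbol_map: SymbolMap | None,
    universe: Sequence[str],
    min_tag_size: int = DEFAULT_MIN_TAG_SIZE,
) -> MappedTag:
    """Translate tag members to platform identifiers and intersect with a universe.

    Returns the mapped member set (possibly empty) plus a flag marking tags
    whose mapped size falls below ``min_tag_size``; flagged tags are excluded
    by matrix builders rather than erroring the whole build.  A ``None``
    symbol map means identifiers are already on the universe's naming scheme.
    """
    if not len(universe):
        raise ValueError("universe must be nonempty")
    universe_set = set(universe)
    if symbol_map is None:
        mapped = frozenset(tag.members) & universe_set
    else:
        mapped_ids: set[str] = set()
        for symbol in tag.members:
            mapped_ids |= symbol_map.platform_ids(symbol)
        mapped = frozenset(mapped_ids) & universe_set
    return MappedTag(
        name=tag.name, members=mapped, flagged=len(mapped) < min_tag_size
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set("()[]{}:;,'\" \t\n")


def _quote_label(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    """Write an ultrametric dendrogram as Newick with branch lengths.

    Branch lengths are parent height minus child height (leaves sit at
    height zero), printed at full float precision so a re-parse recovers the
    merge heights to well under 1e-9.
    """
    n = dendrogram.n_leaves
    heights = dendrogram.node_heights

    def render(node: int) -> str:
        if node < n:
            return _quote_label(dendrogram.leaves[node])
        a, b, h = dendrogram.merges[node - n]
        la = h - heights[a]
        lb = h - heights[b]
        return (
            f"({render(a)}:{la:.17g},{render(b)}:{lb:.17g})"
        )

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(render(dendrogram.root) + ";\n")


def read_newick(path: str | Path) -> Dendrogram:
    """Parse a Newick file (via scikit-bio) back into a Dendrogram."""
    tree = TreeNode.read(str(path), format="newick")
    return Dendrogram.from_treenode(tree)


# ---------------------------------------------------------------------------
# misc report helpers
# ---------------------------------------------------------------------------


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
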