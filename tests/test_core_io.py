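"""Container invariants and text-format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gslhc.core_io import (
    Dendrogram,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GmtParseError,
    InstanceAnnotation,
    MatrixParseError,
    SymbolMap,
    map_tag_to_universe,
    read_gmt,
    read_matrix,
    read_newick,
    write_gmt,
    write_matrix,
    write_newick,
)
from oracles import random_dendrogram


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class TestExpressionMatrix:
    def test_rejects_duplicate_ids_on_either_axis(self):
        with pytest.raises(ValueError, match="duplicate row"):
            ExpressionMatrix(("a", "a"), ("x",), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="duplicate column"):
            ExpressionMatrix(("a", "b"), ("x", "x"), np.zeros((2, 2)))

    def test_rejects_non_finite_values_with_location(self):
        values = np.array([[0.0, np.nan]])
        with pytest.raises(ValueError, match="row 'a'.*column 'y'"):
            ExpressionMatrix(("a",), ("x", "y"), values)

    def test_enrichment_scores_bounded(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            ExpressionMatrix(("a",), ("x",), np.array([[1.5]]), "es")

    def test_transpose_round_trip(self, small_matrix):
        back = small_matrix.transpose().transpose()
        assert back.row_ids == small_matrix.row_ids
        np.testing.assert_array_equal(back.values, small_matrix.values)


class TestDendrogram:
    def test_requires_n_minus_one_merges(self):
        with pytest.raises(ValueError, match="require"):
            Dendrogram(("a", "b", "c"), ((0, 1, 0.1),))

    def test_rejects_decreasing_heights(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            Dendrogram(("a", "b", "c"), ((0, 1, 0.5), (3, 2, 0.2)))

    def test_single_leaf_is_valid(self):
        d = Dendrogram(("solo",), ())
        assert d.root == 0 and d.leaf_order() == ("solo",)

    def test_cophenetic_matrix_reflects_merge_heights(self):
        d = Dendrogram(("a", "b", "c"), ((0, 1, 0.1), (3, 2, 0.6)))
        coph = d.cophenetic_matrix()
        assert coph[0, 1] == pytest.approx(0.1)
        assert coph[0, 2] == coph[1, 2] == pytest.approx(0.6)


class TestInstanceAnnotation:
    def test_duplicate_instance_rejected(self):
        with pytest.raises(ValueError, match="duplicate instance"):
            InstanceAnnotation.from_records(
                [("i1", "d1", "c1"), ("i1", "d2", "c1")]
            )

    def test_lookup_and_groups(self):
        ann = InstanceAnnotation.from_records(
            [("i1", "d1", "c1"), ("i2", "d1", "c2"), ("i3", "d2", "c1")]
        )
        assert ann.drug_of("i2") == "d1"
        assert ann.instances_of_drug("d1") == ("i1", "i2")
        assert ann.drugs == ("d1", "d2")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


class TestGmt:
    def test_duplicate_members_collapse(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("S1\tC2\tg1\tg2\tg2\n")
        coll = read_gmt(path)
        assert coll["S1"].members == frozenset({"g1", "g2"})
        assert coll["S1"].category == "C2"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert len(read_gmt(path)) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tC2\tg1\nS2\tC2\n")
        with pytest.raises(GmtParseError, match="line 2"):
            read_gmt(path)

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tC2\tg1\nS1\tC2\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)

    def test_tab_in_name_rejected_on_write(self, tmp_path):
        coll = GeneSetCollection(
            (GeneSet("bad\tname", "C2", frozenset({"g1"})),)
        )
        with pytest.raises(ValueError, match="delimiter"):
            write_gmt(coll, tmp_path / "x.gmt")

    def test_three_set_round_trip(self, tmp_path, small_collection):
        path = tmp_path / "rt.gmt"
        write_gmt(small_collection, path)
        back = read_gmt(path)
        assert back.names == small_collection.names
        for name in back.names:
            assert back[name].members == small_collection[name].members
            assert back[name].category == small_collection[name].category

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 10_000),
                st.sets(st.integers(0, 500), min_size=1, max_size=20),
            ),
            min_size=1,
            max_size=10,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_identity_random(self, data, tmp_path_factory):
        coll = GeneSetCollection(
            tuple(
                GeneSet(
                    f"SET{idx}",
                    "C4",
                    frozenset(f"gene{m}" for m in members),
                )
                for idx, members in data
            )
        )
        path = tmp_path_factory.mktemp("gmt") / "p.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.names == coll.names
        assert all(back[n].members == coll[n].members for n in coll.names)


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


class TestMatrixIO:
    def test_round_trip(self, tmp_path, small_matrix):
        path = tmp_path / "m.tsv"
        write_matrix(small_matrix, path)
        back = read_matrix(path)
        assert back.row_ids == small_matrix.row_ids
        assert back.col_ids == small_matrix.col_ids
        np.testing.assert_allclose(back.values, small_matrix.values)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 6),
        m=st.integers(1, 6),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_random(self, n, m, seed, tmp_path_factory):
        values = np.random.default_rng(seed).normal(size=(n, m)).round(9)
        matrix = ExpressionMatrix(
            tuple(f"r{i}" for i in range(n)),
            tuple(f"c{j}" for j in range(m)),
            values,
        )
        path = tmp_path_factory.mktemp("mtx") / "m.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path)
        np.testing.assert_allclose(back.values, values, atol=1e-12)

    def test_duplicate_column_id_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("id\tc1\tc1\nr1\t1.0\t2.0\n")
        with pytest.raises(MatrixParseError, match="duplicate column"):
            read_matrix(path)

    def test_non_numeric_cell_reports_location(self, tmp_path):
        path = tmp_path / "n.tsv"
        path.write_text("id\tc1\tc2\nr1\t1.0\toops\n")
        with pytest.raises(MatrixParseError, match="'r1'.*'c2'"):
            read_matrix(path)

    def test_es_kind_range_enforced_on_read(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("id\tc1\nr1\t1.5\n")
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            read_matrix(path, value_kind="es")


# ---------------------------------------------------------------------------
# symbol mapping
# ---------------------------------------------------------------------------


class TestMapTagToUniverse:
    def test_union_then_intersection(self):
        tag = GeneSet("t", "C2", frozenset({"A", "B"}))
        sm = SymbolMap.from_pairs([("A", "p1"), ("A", "p2"), ("B", "p3")])
        mapped = map_tag_to_universe(tag, sm, ("p1", "p3"), min_tag_size=1)
        assert mapped.members == frozenset({"p1", "p3"})
        assert not mapped.flagged

    def test_unmapped_tag_is_empty_and_flagged(self):
        tag = GeneSet("t", "C2", frozenset({"Z"}))
        sm = SymbolMap.from_pairs([("A", "p1")])
        mapped = map_tag_to_universe(tag, sm, ("p1",))
        assert mapped.members == frozenset() and mapped.flagged

    def test_identity_map_leaves_tag_unchanged(self):
        tag = GeneSet("t", "C2", frozenset({"p1", "p2"}))
        sm = SymbolMap.identity(["p1", "p2", "p3"])
        mapped = map_tag_to_universe(tag, sm, ("p1", "p2", "p3"), min_tag_size=1)
        assert mapped.members == tag.members

    def test_idempotent(self):
        tag = GeneSet("t", "C2", frozenset({"A", "B", "C"}))
        sm = SymbolMap.from_pairs([("A", "p1"), ("B", "p2"), ("C", "zzz")])
        universe = ("p1", "p2", "p9")
        once = map_tag_to_universe(tag, sm, universe, min_tag_size=1)
        again = map_tag_to_universe(
            GeneSet("t", "C2", once.members),
            SymbolMap.identity(universe),
            universe,
            min_tag_size=1,
        )
        assert again.members == once.members


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


class TestNewick:
    def test_single_leaf(self, tmp_path):
        path = tmp_path / "one.nwk"
        write_newick(Dendrogram(("leafA",), ()), path)
        assert path.read_text().strip() == "leafA;"
        assert read_newick(path).leaves == ("leafA",)

    def test_three_leaf_round_trip(self, tmp_path):
        d = Dendrogram(("a", "b", "c"), ((0, 1, 0.25), (3, 2, 0.8)))
        path = tmp_path / "t.nwk"
        write_newick(d, path)
        back = read_newick(path)
        assert set(back.leaves) == set(d.leaves)
        order = [back.leaves.index(x) for x in d.leaves]
        np.testing.assert_allclose(
            back.cophenetic_matrix()[np.ix_(order, order)],
            d.cophenetic_matrix(),
            atol=1e-9,
        )

    def test_special_characters_quoted(self, tmp_path):
        d = Dendrogram(("a (x)", "b:1", "c'"), ((0, 1, 0.25), (3, 2, 0.8)))
        path = tmp_path / "q.nwk"
        write_newick(d, path)
        back = read_newick(path)
        assert set(back.leaves) == set(d.leaves)

    def test_round_trip_random_trees(self, rng, tmp_path):
        for trial in range(100):
            n = int(rng.integers(2, 25))
            d = random_dendrogram(rng, n)
            path = tmp_path / f"t{trial}.nwk"
            write_newick(d, path)
            back = read_newick(path)
            order = [back.leaves.index(x) for x in d.leaves]
            np.testing.assert_allclose(
                back.cophenetic_matrix()[np.ix_(order, order)],
                d.cophenetic_matrix(),
                atol=1e-9,
            )
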