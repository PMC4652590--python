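"""Ranking, the KS kernel, and the matrix builders."""

import numpy as np
import pandas as pd
import pytest

from gslhc.core_io import ExpressionMatrix, InstanceAnnotation
from gslhc.enrichment import (
    EmptyIntersectionError,
    average_by_drug,
    drug_level_es,
    drug_es_matrix,
    ks_enrichment_score,
    rank_profile,
    tag_instance_es_matrix,
    top_variance_select,
)
from oracles import naive_ks


class TestRankProfile:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"g1": 2.0, "g2": -1.0, "g3": 0.5}, ("g1", "g3", "g2")),
            ({"g1": 1.0, "g2": 1.0}, ("g1", "g2")),  # stable tie order
        ],
    )
    def test_descending_order_stable_on_ties(self, scores, expected):
        assert rank_profile(scores).ordered_ids == expected

    def test_reversing_values_reverses_ranking(self):
        scores = {"a": 3.0, "b": 1.0, "c": 2.0}
        fwd = rank_profile(scores).ordered_ids
        rev = rank_profile({k: -v for k, v in scores.items()}).ordered_ids
        assert rev == fwd[::-1]

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rank_profile({"a": 1.0, "b": float("nan")})


class TestKsEnrichmentScore:
    @pytest.fixture()
    def rp4(self):
        return rank_profile({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})

    def test_top_pair_scores_half(self, rp4):
        assert ks_enrichment_score(rp4, {"g1", "g2"}) == pytest.approx(0.5)

    def test_bottom_pair_scores_minus_three_quarters(self, rp4):
        assert ks_enrichment_score(rp4, {"g3", "g4"}) == pytest.approx(-0.75)

    @pytest.mark.parametrize("n,t", [(5, 1), (8, 3), (20, 7), (50, 49)])
    def test_top_prefix_scores_one_minus_t_over_n(self, n, t):
        rp = rank_profile({f"g{i}": float(n - i) for i in range(n)})
        members = {f"g{i}" for i in range(t)}
        assert ks_enrichment_score(rp, members) == pytest.approx(1 - t / n)

    def test_matches_naive_position_walk(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 51))
            t = int(rng.integers(1, n))
            rp = rank_profile(
                {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
            )
            members = set(rng.choice(list(rp.ordered_ids), t, replace=False))
            positions = sorted(
                rp.ordered_ids.index(m) + 1 for m in members
            )
            assert ks_enrichment_score(rp, members) == pytest.approx(
                naive_ks(positions, n), abs=0
            )

    def test_reversal_swaps_up_and_down_deviations(self, rng):
        """Reversing the ranked list swaps the two one-sided deviations up
        to a single 1/N boundary term (a' = b - 1/N, b' = a + 1/N), so the
        score negates to within 1/N away from a/b near-ties."""

        def deviations(positions, n):
            pos = np.asarray(sorted(positions), dtype=float)
            t = len(pos)
            j = np.arange(1, t + 1)
            return np.max(j / t - pos / n), np.max(pos / n - (j - 1) / t)

        for _ in range(200):
            n = int(rng.integers(3, 40))
            t = int(rng.integers(1, n))
            values = rng.normal(size=n)
            ids = [f"g{i}" for i in range(n)]
            members = set(rng.choice(ids, t, replace=False))
            rp_f = rank_profile(dict(zip(ids, values)))
            rp_r = rank_profile(dict(zip(ids, -values)))
            pos_f = [rp_f.ordered_ids.index(m) + 1 for m in members]
            pos_r = [rp_r.ordered_ids.index(m) + 1 for m in members]
            a, b = deviations(pos_f, n)
            a_rev, b_rev = deviations(pos_r, n)
            assert a_rev == pytest.approx(b - 1 / n, abs=1e-12)
            assert b_rev == pytest.approx(a + 1 / n, abs=1e-12)
            fwd = ks_enrichment_score(rp_f, members)
            rev = ks_enrichment_score(rp_r, members)
            if abs(a - b) > 2 / n + 1e-12:
                assert fwd + rev == pytest.approx(-1 / n, abs=1e-12)
                assert np.sign(fwd) == -np.sign(rev)

    def test_empty_intersection_distinct_error(self, rp4):
        with pytest.raises(EmptyIntersectionError):
            ks_enrichment_score(rp4, {"absent"})

    def test_full_universe_rejected(self, rp4):
        with pytest.raises(ValueError, match="smaller than the universe"):
            ks_enrichment_score(rp4, {"g1", "g2", "g3", "g4"})

    def test_weighted_running_sum_hand_cases(self):
        rp = rank_profile({"g1": 2.0, "g2": 1.0, "g3": 0.0})
        # hit g1: increment |2|/2 = 1 -> max deviation +1
        assert ks_enrichment_score(rp, {"g1"}, weight_exponent=1.0) == 1.0
        # hit g3 (score 0, zero weight): falls back to 1/t steps; running
        # sum dips to -1 before recovering at the last position
        assert ks_enrichment_score(rp, {"g3"}, weight_exponent=1.0) == -1.0


class TestTagInstanceEsMatrix:
    def test_entries_equal_scalar_kernel(self, small_matrix, small_collection):
        build = tag_instance_es_matrix(
            small_matrix, small_collection, min_tag_size=1
        )
        for tag in build.matrix.row_ids:
            members = small_collection[tag].members
            for inst in build.matrix.col_ids:
                expected = ks_enrichment_score(
                    rank_profile(small_matrix.col(inst)), members
                )
                got = build.matrix.values[
                    build.matrix.row_index(tag), build.matrix.col_index(inst)
                ]
                assert got == pytest.approx(expected, abs=0)

    def test_all_entries_within_unit_interval(self, rng):
        from gslhc.synthetic import generate_genesets

        expr = ExpressionMatrix(
            tuple(f"g{i:02d}" for i in range(1, 31)),  # generator's naming
            tuple(f"i{j}" for j in range(8)),
            rng.normal(size=(30, 8)),
        )
        tags = generate_genesets(30, 10, (3, 8), seed=1, gene_prefix="g")
        build = tag_instance_es_matrix(expr, tags, min_tag_size=1)
        assert np.abs(build.matrix.values).max() <= 1.0

    def test_small_tags_excluded_with_reason(self, small_matrix, small_collection):
        build = tag_instance_es_matrix(
            small_matrix, small_collection, min_tag_size=3
        )
        assert set(build.matrix.row_ids) == {"S3"}
        assert "S1" in build.exclusions and "S2" in build.exclusions

    def test_column_deletion_leaves_other_columns_unchanged(
        self, small_matrix, small_collection
    ):
        full = tag_instance_es_matrix(
            small_matrix, small_collection, min_tag_size=1
        ).matrix
        reduced = tag_instance_es_matrix(
            small_matrix.subset_cols(["i1", "i3"]),
            small_collection,
            min_tag_size=1,
        ).matrix
        np.testing.assert_array_equal(
            reduced.values,
            full.values[:, [0, 2]],
        )

    def test_zero_surviving_tags_is_error(self, small_matrix, small_collection):
        with pytest.raises(ValueError, match="no tag survives"):
            tag_instance_es_matrix(
                small_matrix, small_collection, min_tag_size=10
            )


class TestAverageByDrug:
    @pytest.fixture()
    def annotation(self):
        return InstanceAnnotation.from_records(
            [("i1", "dA", "c1"), ("i2", "dA", "c2"), ("i3", "dB", "c1")]
        )

    def test_single_instance_drug_copied(self, small_matrix, annotation):
        out = average_by_drug(small_matrix, annotation)
        np.testing.assert_array_equal(
            out.values[:, out.col_index("dB")], small_matrix.values[:, 2]
        )

    def test_mean_of_two_instances(self, small_matrix, annotation):
        out = average_by_drug(small_matrix, annotation)
        np.testing.assert_allclose(
            out.values[:, out.col_index("dA")],
            small_matrix.values[:, :2].mean(axis=1),
        )

    def test_column_order_invariance(self, small_matrix, annotation):
        out1 = average_by_drug(small_matrix, annotation)
        shuffled = small_matrix.subset_cols(["i3", "i1", "i2"])
        out2 = average_by_drug(shuffled, annotation)
        for drug in out1.col_ids:
            np.testing.assert_allclose(
                out1.values[:, out1.col_index(drug)],
                out2.values[:, out2.col_index(drug)],
            )

    def test_unannotated_column_is_error(self, small_matrix):
        ann = InstanceAnnotation.from_records([("i1", "dA", "c1")])
        with pytest.raises(KeyError, match="missing from annotation"):
            average_by_drug(small_matrix, ann)


class TestDrugLevelEs:
    def test_reduces_to_shared_kernel(self, rng):
        ids = [f"i{k}" for k in range(12)]
        vd = pd.Series(rng.normal(size=12), index=ids)
        group = set(rng.choice(ids, 4, replace=False))
        assert drug_level_es(vd, group) == ks_enrichment_score(
            rank_profile(vd), group
        )

    def test_top_pair_of_six(self):
        vd = pd.Series([6.0, 5, 4, 3, 2, 1], index=[f"i{k}" for k in range(6)])
        assert drug_level_es(vd, {"i0", "i1"}) == pytest.approx(2 / 3)

    def test_bottom_pair_of_six(self):
        vd = pd.Series([6.0, 5, 4, 3, 2, 1], index=[f"i{k}" for k in range(6)])
        assert drug_level_es(vd, {"i4", "i5"}) == pytest.approx(-5 / 6)

    @pytest.mark.parametrize("n", [4, 10, 25])
    def test_single_top_instance(self, n):
        vd = pd.Series(
            np.arange(n, 0, -1, dtype=float), index=[f"i{k}" for k in range(n)]
        )
        assert drug_level_es(vd, {"i0"}) == pytest.approx(1 - 1 / n)

    def test_unknown_instance_rejected(self):
        vd = pd.Series([1.0, 2.0], index=["i0", "i1"])
        with pytest.raises(KeyError, match="unknown instance"):
            drug_level_es(vd, {"i0", "nope"})

    def test_matrix_builder_matches_scalar(self, rng):
        es = ExpressionMatrix(
            tuple(f"t{k}" for k in range(5)),
            tuple(f"i{k}" for k in range(9)),
            np.clip(rng.normal(scale=0.3, size=(5, 9)), -1, 1),
            "es",
        )
        ann = InstanceAnnotation.from_records(
            [(f"i{k}", f"d{k % 3}", "c1") for k in range(9)]
        )
        out = drug_es_matrix(es, ann)
        for tag in es.row_ids:
            for drug in out.col_ids:
                expected = drug_level_es(
                    es.row(tag), set(ann.instances_of_drug(drug))
                )
                got = out.values[out.row_index(tag), out.col_index(drug)]
                assert got == pytest.approx(expected, abs=0)


class TestTopVarianceSelect:
    def test_constant_row_never_selected(self, rng):
        values = rng.normal(size=(4, 5))
        values[2] = 0.7
        expr = ExpressionMatrix(("a", "b", "c", "d"), tuple("vwxyz"), values)
        out = top_variance_select(expr, 3)
        assert "c" not in out.row_ids

    def test_k_equal_rows_reorders_by_variance(self, small_matrix):
        out = top_variance_select(small_matrix, small_matrix.shape[0])
        assert set(out.row_ids) == set(small_matrix.row_ids)
        variances = out.values.var(axis=1, ddof=1)
        assert np.all(np.diff(variances) <= 1e-12)

    def test_matches_sort_oracle(self, rng):
        values = rng.normal(size=(5, 6))
        expr = ExpressionMatrix(tuple("abcde"), tuple("uvwxyz"), values)
        out = top_variance_select(expr, 3)
        order = np.argsort(-values.var(axis=1, ddof=1), kind="stable")[:3]
        assert out.row_ids == tuple(expr.row_ids[i] for i in order)

    @pytest.mark.parametrize("k", [0, -1, 99])
    def test_k_out_of_range(self, small_matrix, k):
        with pytest.raises(ValueError):
            top_variance_select(small_matrix, k)
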