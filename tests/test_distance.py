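"""Input-vector distances, the shuffle null, z-scoring and pair summaries."""

import itertools

import numpy as np
import pytest

from cohortwiring.distance import (
    InputMatrix,
    build_input_matrix,
    euclidean_distances,
    exhaustive_null,
    pair_summaries,
    run_distance_analysis,
    shuffle_null,
    shuffle_rows,
    zscore_and_call,
)
from cohortwiring.model import Catalog

from .conftest import record, table_of


def matrix(values, mode="count"):
    values = np.asarray(values)
    return InputMatrix(
        analyzed=[f"n{i}" for i in range(values.shape[0])],
        universe=[f"u{j}" for j in range(values.shape[1])],
        values=values,
        mode=mode,
    )


class TestBuildInputMatrix:
    def setup_method(self):
        self.sub = table_of(("a", "x", 2), ("b", "x", 1), ("a", "y", 3))

    def test_count_mode_tabulation(self):
        m = build_input_matrix(self.sub, ["x", "y"])
        assert m.universe == ["a", "b"]
        np.testing.assert_array_equal(m.values, [[2, 1], [3, 0]])

    def test_binary_mode(self):
        m = build_input_matrix(self.sub, ["x", "y"], mode="binary")
        np.testing.assert_array_equal(m.values, [[1, 1], [1, 0]])

    def test_binarize_idempotent(self):
        m = build_input_matrix(self.sub, ["x", "y"])
        b = m.binarize()
        np.testing.assert_array_equal(b.values, b.binarize().values)

    def test_dropout_with_no_matching_sources_flags_all_rows(self):
        cat = Catalog([record(n) for n in ("a", "b", "x", "y")])
        m = build_input_matrix(self.sub, ["x", "y"], dropout="sensory_only", catalog=cat)
        assert m.universe == []
        assert set(m.zero_input_rows) == {"x", "y"}

    def test_dropout_requires_catalog(self):
        with pytest.raises(ValueError, match="catalog"):
            build_input_matrix(self.sub, ["x"], dropout="sensory_only")

    def test_no_all_zero_columns(self, sharp_system):
        ts = sharp_system.target_set()
        m = build_input_matrix(sharp_system.table.onto(ts.members), ts.members)
        assert (m.values.sum(axis=0) > 0).all()


class TestEuclidean:
    def test_identical_rows_zero(self):
        d = euclidean_distances(matrix([[1, 2], [1, 2]]))
        assert d[0, 1] == 0.0

    def test_three_four_five(self):
        d = euclidean_distances(matrix([[3, 0], [0, 4]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        vals = rng.integers(0, 9, size=(4, 6))
        d = euclidean_distances(matrix(vals))
        for i in range(4):
            for j in range(4):
                naive = np.sqrt(sum((vals[i, k] - vals[j, k]) ** 2 for k in range(6)))
                assert d[i, j] == pytest.approx(naive)


class TestShuffleNull:
    def test_row_value_multisets_conserved(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 20, size=(5, 30)).astype(float)
        for _ in range(100):
            sh = shuffle_rows(vals, rng)
            for i in range(5):
                assert sorted(sh[i]) == sorted(vals[i])

    def test_single_column_universe_has_zero_sd(self):
        m = matrix([[3], [5]])
        mean, sd, _ = shuffle_null(m, n_perm=10, seed=1)
        assert sd[0, 1] == 0.0
        assert mean[0, 1] == pytest.approx(2.0)

    def test_exhaustive_two_singleton_rows(self):
        # two rows each with one synapse in different columns; the 4 joint
        # permutations give distances {0, 0, sqrt(2), sqrt(2)}
        m = matrix([[1, 0], [0, 1]])
        mean, sd = exhaustive_null(m)
        assert mean[0, 1] == pytest.approx(np.sqrt(2) / 2)
        assert sd[0, 1] == pytest.approx(np.sqrt(2) / 2)

    def test_monte_carlo_approaches_exhaustive(self):
        rng = np.random.default_rng(5)
        m = matrix(rng.integers(0, 5, size=(3, 4)))
        ex_mean, ex_sd = exhaustive_null(m)
        err = []
        for n_perm in (100, 2000):
            mc_mean, _, _ = shuffle_null(m, n_perm=n_perm, seed=9)
            err.append(np.abs(mc_mean - ex_mean).max())
        assert err[1] < err[0]

    def test_n_perm_below_two_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            shuffle_null(matrix([[1, 2], [3, 4]]), n_perm=1)

    def test_determinism(self):
        m = matrix(np.arange(12).reshape(3, 4))
        a = shuffle_null(m, n_perm=50, seed=7)
        b = shuffle_null(m, n_perm=50, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestZScore:
    def test_equal_to_null_mean_means_no_calls(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = zscore_and_call(d, d.copy(), np.full((2, 2), 0.5), ["a", "b"])
        assert res.z[0, 1] == 0.0
        assert not res.similar.any() and not res.different.any()

    def test_three_sigma_below_is_similar(self):
        null_mean = np.full((2, 2), 10.0)
        null_sd = np.full((2, 2), 1.0)
        d = np.full((2, 2), 7.0)
        res = zscore_and_call(d, null_mean, null_sd, ["a", "b"])
        assert res.z[0, 1] == pytest.approx(-3.0)
        assert res.similar[0, 1] and not res.different[0, 1]

    def test_zero_sd_pair_is_undefined_never_significant(self):
        res = zscore_and_call(
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.zeros((2, 2)), np.zeros((2, 2)), ["a", "b"],
        )
        assert res.undefined[0, 1]
        assert not res.similar[0, 1] and not res.different[0, 1]
        assert np.isnan(res.z[0, 1])

    def test_threshold_follows_alpha(self):
        d = np.zeros((2, 2))
        res = zscore_and_call(d, d, np.ones((2, 2)), ["a", "b"], alpha=0.01)
        assert res.z_threshold == pytest.approx(2.5758, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            zscore_and_call(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((3, 3)), ["a", "b"])

    def test_similar_and_different_never_overlap(self, sharp_system):
        ts = sharp_system.target_set()
        sub = sharp_system.table.onto(ts.members)
        res = run_distance_analysis(sub, ts.members, catalog=sharp_system.catalog,
                                    n_perm=50, seed=3)
        assert not (res.similar & res.different).any()
        assert np.allclose(res.d, res.d.T)


class TestPairSummaries:
    def make_catalog(self):
        recs = []
        for rank, (a, b) in enumerate([("x_L", "x_R"), ("y_L", "y_R"), ("z_L", "z_R")], 1):
            cohort = "early" if rank <= 2 else "late"
            recs.append(record(a, homolog_id=b, lineage="NB", hemilineage="NotchOFF",
                               birth_order=rank, cohort=cohort))
            recs.append(record(b, side="R", homolog_id=a, lineage="NB",
                               hemilineage="NotchOFF", birth_order=rank, cohort=cohort))
        recs.append(record("mid", side="M", homolog_id="mid"))
        return Catalog(recs)

    def make_result(self, analyzed):
        n = len(analyzed)
        rng = np.random.default_rng(1)
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        d = np.abs(z)
        return zscore_and_call(d, np.zeros((n, n)), np.ones((n, n)), analyzed)

    def test_following_pairs_are_consecutive_same_side(self):
        analyzed = ["x_L", "y_L", "z_L", "x_R", "y_R", "z_R", "mid"]
        res = self.make_result(analyzed)
        out = pair_summaries(res, self.make_catalog())
        got = {(r.a, r.b) for r in out.following.itertuples()}
        assert got == {("x_L", "y_L"), ("y_L", "z_L"), ("x_R", "y_R"), ("y_R", "z_R")}

    def test_left_right_pairs_exclude_midline(self):
        analyzed = ["x_L", "x_R", "mid"]
        out = pair_summaries(self.make_result(analyzed), self.make_catalog())
        assert {(r.a, r.b) for r in out.left_right.itertuples()} == {("x_L", "x_R")}

    def test_cohort_grouping(self):
        analyzed = ["x_L", "x_R", "z_L", "z_R"]
        out = pair_summaries(self.make_result(analyzed), self.make_catalog())
        groups = dict(zip(zip(out.left_right.a, out.left_right.b), out.left_right.cohort_group))
        assert groups[("x_L", "x_R")] == "early"
        assert groups[("z_L", "z_R")] == "late"


def test_full_run_is_deterministic(sharp_system):
    ts = sharp_system.target_set()
    sub = sharp_system.table.onto(ts.members)
    kw = dict(catalog=sharp_system.catalog, n_perm=30, seed=21)
    a = run_distance_analysis(sub, ts.members, **kw)
    b = run_distance_analysis(sub, ts.members, **kw)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.similar, b.similar)
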