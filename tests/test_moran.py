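import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarmap import (lisa, local_moran, make_lattice, make_weights, morans_i,
                    morans_i_test)


def brute_force_moran(x, Wdense):
    """Independent double-loop implementation of the global statistic."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    s0 = Wdense.sum()
    num = sum(Wdense[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / s0 * num / (z**2).sum()


class TestWeights:
    def test_path_graph_row_standardized(self):
        w = make_weights(make_lattice(1, 3, "rook"), "row-standardized")
        m = w.matrix.toarray()
        assert m[1, 0] == 0.5 and m[1, 2] == 0.5
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_binary_s0_twice_edges(self):
        g = make_lattice(3, 3, "queen")
        w = make_weights(g, "binary")
        assert w.s0 == 2 * len(g.edges)

    def test_rows_sum_to_one(self):
        w = make_weights(make_lattice(2, 2, "rook"), "row-standardized")
        assert np.allclose(w.matrix.toarray().sum(axis=1), 1.0)

    def test_isolated_tract_zero_row(self):
        from sarmap import AdjacencyGraph
        g = AdjacencyGraph(("a", "b", "c"), frozenset({frozenset({"a", "b"})}))
        with pytest.warns(UserWarning, match="isolated"):
            w = make_weights(g)
        assert w.matrix.toarray()[2].sum() == 0


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        w = make_weights(make_lattice(2, 2, "rook"))
        assert morans_i([1.0, -1.0, -1.0, 1.0], w) == pytest.approx(-1.0)
        wb = make_weights(make_lattice(2, 2, "rook"), "binary")
        assert morans_i([1.0, -1.0, -1.0, 1.0], wb) == pytest.approx(-1.0)

    def test_iid_mean_matches_randomization_expectation(self):
        g = make_lattice(5, 5, "queen")
        w = make_weights(g)
        rng = np.random.default_rng(0)
        vals = [morans_i(rng.normal(size=g.n), w) for _ in range(200)]
        e_i = -1.0 / (g.n - 1)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - e_i) < 3 * se

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force(self, seed):
        g = make_lattice(3, 4, "queen")
        w = make_weights(g)
        x = np.random.default_rng(seed).normal(size=g.n)
        assert morans_i(x, w) == pytest.approx(
            brute_force_moran(x, w.matrix.toarray()), abs=1e-12)

    def test_constant_values_rejected(self):
        w = make_weights(make_lattice(2, 2, "rook"))
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(4), w)


class TestMoranTest:
    def test_pseudo_p_matches_exhaustive_enumeration(self):
        # n = 5 tracts: all 120 relabelings enumerable exactly
        g = make_lattice(1, 5, "rook")
        w = make_weights(g)
        x = np.array([1.0, 2.0, 0.5, 3.0, -1.0])
        i_obs = morans_i(x, w)
        Wd = w.matrix.toarray()
        perms = [brute_force_moran(np.array(p), Wd)
                 for p in itertools.permutations(x)]
        exact_p = np.mean(np.abs(perms) >= abs(i_obs) - 1e-12)
        res = morans_i_test(x, w, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_autocorrelated_surface_detected(self):
        from sarmap.synthetic import simulate_icar_field
        g = make_lattice(15, 15, "queen")
        w = make_weights(g)
        u = simulate_icar_field(g, 1.0, seed=1)
        res = morans_i_test(u, w, n_perm=199, seed=0)
        assert res.p_value <= 0.01

    def test_normal_method_consistent_with_permutation(self):
        g = make_lattice(6, 6, "queen")
        w = make_weights(g)
        x = np.random.default_rng(3).normal(size=g.n)
        perm = morans_i_test(x, w, n_perm=9999, seed=0)
        norm = morans_i_test(x, w, method="normal")
        assert norm.expected_i == pytest.approx(-1.0 / (g.n - 1))
        assert norm.z_score == pytest.approx(perm.z_score, abs=0.4)

    def test_reproducible_and_validated(self):
        g = make_lattice(4, 4, "rook")
        w = make_weights(g)
        x = np.random.default_rng(1).normal(size=g.n)
        a = morans_i_test(x, w, n_perm=199, seed=5)
        b = morans_i_test(x, w, n_perm=199, seed=5)
        assert a.p_value == b.p_value and a.z_score == b.z_score
        with pytest.raises(ValueError):
            morans_i_test(x, w, n_perm=50)


class TestLocalMoran:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sum_identity_row_standardized(self, seed):
        g = make_lattice(4, 5, "queen")
        w = make_weights(g)
        x = np.random.default_rng(seed).normal(size=g.n)
        assert local_moran(x, w).sum() == pytest.approx(g.n * morans_i(x, w),
                                                        abs=1e-10)

    def test_tract_at_mean_is_zero(self):
        w = make_weights(make_lattice(1, 3, "rook"))
        li = local_moran(np.array([1.0, 2.0, 3.0]), w)
        assert li[1] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_all_negative(self):
        w = make_weights(make_lattice(2, 2, "rook"))
        assert np.all(local_moran(np.array([1.0, -1.0, -1.0, 1.0]), w) < 0)


class TestLisa:
    def test_single_outlier_classified_high_low(self):
        g = make_lattice(5, 5, "rook")
        w = make_weights(g)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.01, g.n)
        center = list(g.tract_ids).index("r2c2")
        x[center] = 100.0
        res = lisa(x, w, n_perm=999, alpha=0.05, seed=0)
        if res.p_value[center] <= 0.05:
            assert res.cluster[center] == "high-low"

    def test_cluster_classes_match_sign_rule(self):
        from sarmap.synthetic import simulate_icar_field
        g = make_lattice(8, 8, "queen")
        w = make_weights(g)
        x = simulate_icar_field(g, 0.5, seed=4)
        res = lisa(x, w, n_perm=199, seed=1)
        for i_local, cls in zip(res.i_local, res.cluster):
            if cls in ("high-high", "low-low"):
                assert i_local > 0
            elif cls in ("high-low", "low-high"):
                assert i_local < 0

    def test_counts_sum_to_n_and_reproducible(self):
        g = make_lattice(4, 4, "queen")
        w = make_weights(g)
        x = np.random.default_rng(5).normal(size=g.n)
        a = lisa(x, w, n_perm=199, seed=3)
        b = lisa(x, w, n_perm=199, seed=3)
        assert sum(a.counts().values()) == g.n
        np.testing.assert_array_equal(a.p_value, b.p_value)

    def test_fdr_is_more_conservative(self):
        from sarmap.synthetic import simulate_icar_field
        g = make_lattice(8, 8, "queen")
        w = make_weights(g)
        x = simulate_icar_field(g, 1.0, seed=6)
        plain = lisa(x, w, n_perm=999, seed=0)
        adj = lisa(x, w, n_perm=999, seed=0, fdr=True)
        n_sig = lambda r: (r.cluster != "not-significant").sum()  # noqa: E731
        assert n_sig(adj) <= n_sig(plain)

    def test_invalid_arguments(self):
        w = make_weights(make_lattice(2, 2, "rook"))
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            lisa(x, w, n_perm=10)
        with pytest.raises(ValueError):
            lisa(x, w, alpha=1.5)
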