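"""Blomberg's K and the tip-shuffle permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import urbanphylo as up
from urbanphylo.signal import DegenerateTraitError, SingularCovarianceError

from conftest import balanced_newick, star_newick
from oracles import blomberg_k as oracle_k, gls_mean as oracle_mean


class TestPhylogeneticMean:
    def test_identity_covariance_is_arithmetic_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        assert up.phylogenetic_mean(x, np.eye(3)) == pytest.approx(3.0)

    def test_constant_trait_returns_constant(self, worked_cov):
        assert up.phylogenetic_mean(np.full(3, 7.5), worked_cov) == pytest.approx(7.5)

    def test_worked_tree_matches_oracle(self, worked_cov):
        x = np.array([1.0, 2.0, 4.0])
        a = up.phylogenetic_mean(x, worked_cov)
        assert a == pytest.approx(oracle_mean(worked_cov.matrix, x), abs=1e-12)
        assert a == pytest.approx(18 / 7)  # hand value: weights (2,2,3)/7

    def test_singular_covariance_rejected(self):
        V = np.array([[1.0, 1.0], [1.0, 1.0]])  # identical tips
        with pytest.raises(SingularCovarianceError, match="sanitize"):
            up.phylogenetic_mean(np.array([0.0, 1.0]), V)


class TestBlombergK:
    @pytest.mark.parametrize("n,branch", [(4, 1.0), (10, 0.5), (25, 3.0)])
    def test_star_tree_k_is_one(self, n, branch, rng):
        cov = up.compute_vcv(up.parse_newick(star_newick(n, branch)))
        x = rng.standard_normal(n)
        assert up.blomberg_k(x, cov) == pytest.approx(1.0, abs=1e-12)

    def test_worked_tree_matches_oracle(self, worked_cov):
        x = np.array([1.0, 2.0, 4.0])
        k = up.blomberg_k(x, worked_cov)
        assert k == pytest.approx(oracle_k(worked_cov.matrix, x), abs=1e-12)
        assert k == pytest.approx(1.234375, abs=1e-9)  # frozen hand value

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(-100, 100, allow_nan=False),
        b=st.floats(min_value=0.01, max_value=100).flatmap(
            lambda v: st.sampled_from([v, -v])
        ),
    )
    def test_affine_invariance(self, worked_cov, a, b):
        x = np.array([1.0, 2.0, 4.0])
        k0 = up.blomberg_k(x, worked_cov)
        k1 = up.blomberg_k(a + b * x, worked_cov)
        assert k1 == pytest.approx(k0, rel=1e-10)

    def test_random_tree_matches_oracle(self, yule50, rng):
        cov = up.compute_vcv(yule50)
        x = rng.standard_normal(50)
        assert up.blomberg_k(x, cov) == pytest.approx(
            oracle_k(cov.matrix, x), rel=1e-9
        )

    def test_constant_trait_is_error_not_zero(self, worked_cov):
        with pytest.raises(DegenerateTraitError):
            up.blomberg_k(np.full(3, 1.0), worked_cov)

    def test_white_noise_on_deep_tree_has_low_k(self, rng):
        # no phylogenetic structure in the trait => K well below Brownian
        cov = up.compute_vcv(up.parse_newick(balanced_newick(6)))  # 64 tips
        ks = [up.blomberg_k(rng.standard_normal(64), cov) for _ in range(300)]
        assert np.mean(ks) < 0.5


class TestPermutation:
    def test_perfectly_clustered_trait_hits_p_floor(self):
        # clade-indicator trait on a deep balanced tree: the observed MSE
        # beats every shuffle, so the add-one rule gives its floor
        tree = up.parse_newick(balanced_newick(5))
        cov = up.compute_vcv(tree)
        x = np.array([0.0] * 16 + [1.0] * 16)
        _, p = up.permutation_pvalue(x, cov, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_two_tip_symmetry_gives_p_one(self):
        # both orderings of 2 values give identical MSE => all null ties => p = 1
        cov = up.compute_vcv(up.parse_newick("(A:1,B:1);"))
        _, p = up.permutation_pvalue(np.array([0.0, 1.0]), cov, n_perm=199, seed=0)
        assert p == 1.0

    def test_deterministic_under_seed(self, yule50, rng):
        cov = up.compute_vcv(yule50)
        x = rng.standard_normal(50)
        k1, p1 = up.permutation_pvalue(x, cov, n_perm=199, seed=42)
        k2, p2 = up.permutation_pvalue(x, cov, n_perm=199, seed=42)
        k3, p3 = up.permutation_pvalue(x, cov, n_perm=199, seed=43)
        assert (k1, p1) == (k2, p2)
        assert k3 == k1  # K never depends on the seed
        assert p1 >= 1 / 200

    def test_k_statistic_option_agrees_on_strong_signal(self):
        tree = up.parse_newick(balanced_newick(5))
        cov = up.compute_vcv(tree)
        x = np.arange(32.0)
        _, p_mse = up.permutation_pvalue(x, cov, n_perm=199, seed=7, statistic="mse")
        _, p_k = up.permutation_pvalue(x, cov, n_perm=199, seed=7, statistic="k")
        assert abs(p_mse - p_k) <= 0.05

    def test_null_pvalues_are_uniform(self, yule50):
        # KS distance of null p-values from U(0,1) below the 1% critical value
        cov = up.compute_vcv(up.prune_to_taxa(yule50, yule50.tip_names[:30]))
        rng = np.random.default_rng(77)
        pvals = []
        for rep in range(500):
            x = rng.standard_normal(30)
            _, p = up.permutation_pvalue(x, cov, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").statistic
        crit_1pct = 1.63 / np.sqrt(500)
        assert ks < crit_1pct

    def test_invalid_n_perm(self, worked_cov):
        with pytest.raises(ValueError):
            up.permutation_pvalue(np.array([1.0, 2.0, 4.0]), worked_cov, n_perm=0)


class TestSignalTest:
    def test_small_group_flagged_not_computed(self, worked_cov):
        res = up.signal_test(
            np.array([1.0, 2.0, 4.0]), worked_cov,
            trait_name="leaf_N", group="urban", habit="tree", seed=1,
        )
        assert res.note == "insufficient_n"
        assert res.k is None and res.p_value is None

    def test_degenerate_trait_flagged(self):
        cov = up.compute_vcv(up.parse_newick(star_newick(5)))
        res = up.signal_test(
            np.full(5, 3.0), cov,
            trait_name="leaf_C", group="rural", habit="shrub", seed=1,
        )
        assert res.note == "degenerate_trait"

    def test_cell_seed_is_stable_and_distinct(self):
        s1 = up.derive_cell_seed(7, "tree", "urban", "leaf_N")
        s2 = up.derive_cell_seed(7, "tree", "urban", "leaf_N")
        s3 = up.derive_cell_seed(7, "tree", "urban", "leaf_C")
        s4 = up.derive_cell_seed(8, "tree", "urban", "leaf_N")
        assert s1 == s2
        assert len({s1, s3, s4}) == 3
        assert 0 <= s1 < 2**31
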