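import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import codiversity as cd
from conftest import random_grouped


class TestSimpson:
    def test_uniform_18_causes_is_17_18(self, scheme18):
        d = cd.CauseDistribution(scheme18, np.full(18, 1 / 18))
        assert cd.simpson(d) == pytest.approx(17 / 18, abs=1e-15)

    def test_degenerate_distribution_is_zero(self, scheme18):
        shares = np.zeros(18)
        shares[0] = 1.0
        assert cd.simpson(cd.CauseDistribution(scheme18, shares)) == 0.0

    def test_two_cause_example(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.7, 0.3]))
        assert cd.simpson(d) == pytest.approx(0.42, abs=1e-15)

    def test_bounded_by_k_minus_1_over_k(self, scheme18):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(rng.uniform(0.1, 3, 18))
            s = cd.simpson(cd.CauseDistribution(scheme18, p))
            assert 0.0 <= s <= 17 / 18 + 1e-12

    def test_monte_carlo_sampling_oracle(self, scheme18):
        """The index equals the probability that two independently drawn
        deaths differ in cause, to Monte-Carlo accuracy."""
        rng = np.random.default_rng(42)
        counts = rng.integers(1, 50, size=18).astype(float)
        p = counts / counts.sum()
        s = cd.simpson(cd.CauseDistribution(scheme18, p))
        ndraw = 1_000_000
        a = rng.choice(18, size=ndraw, p=p)
        b = rng.choice(18, size=ndraw, p=p)
        phat = (a != b).mean()
        se = np.sqrt(s * (1 - s) / ndraw)
        assert abs(phat - s) < 3 * se


class TestPairDiversity:
    def test_self_pair_equals_simpson(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.6, 0.4]))
        assert cd.pair_diversity(d, d) == cd.simpson(d)

    def test_disjoint_supports_give_one(self, scheme2):
        a = cd.CauseDistribution(scheme2, np.array([1.0, 0.0]))
        b = cd.CauseDistribution(scheme2, np.array([0.0, 1.0]))
        assert cd.pair_diversity(a, b) == 1.0

    def test_worked_cross_product(self, scheme2):
        a = cd.CauseDistribution(scheme2, np.array([0.5, 0.5]))
        b = cd.CauseDistribution(scheme2, np.array([0.75, 0.25]))
        assert cd.pair_diversity(a, b) == pytest.approx(0.5, abs=1e-15)
        assert cd.pair_diversity(b, a) == cd.pair_diversity(a, b)

    def test_scheme_mismatch_rejected(self, scheme2, scheme18):
        a = cd.CauseDistribution(scheme2, np.array([0.5, 0.5]))
        b = cd.CauseDistribution(scheme18, np.full(18, 1 / 18))
        with pytest.raises(cd.ValidationError):
            cd.pair_diversity(a, b)


class TestPooledAndDecomposition:
    def test_pooled_worked_instance(self, worked_gm):
        pooled = cd.pooled_distribution(worked_gm)
        np.testing.assert_allclose(pooled.shares, [2 / 3, 1 / 3], atol=1e-15)
        assert pooled.n == 60

    def test_single_group_pooled_is_identity(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.3, 0.7]))
        gm = cd.GroupedMortality(scheme2, ("g",), np.array([1.0]), (d,))
        np.testing.assert_array_equal(cd.pooled_distribution(gm).shares, d.shares)
        dec = cd.within_between(gm)
        assert dec.S_B == 0.0
        assert dec.S_W == pytest.approx(dec.S, abs=1e-15)

    def test_worked_decomposition(self, worked_gm):
        dec = cd.within_between(worked_gm)
        assert dec.S == pytest.approx(4 / 9, abs=1e-12)
        assert dec.S_W == pytest.approx(2 / 9, abs=1e-12)
        assert dec.S_B == pytest.approx(2 / 9, abs=1e-12)

    def test_identical_equal_weight_groups_split_evenly(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.6, 0.4]))
        gm = cd.GroupedMortality(
            scheme2, ("a", "b"), np.array([0.5, 0.5]), (d, d)
        )
        dec = cd.within_between(gm)
        s = cd.simpson(d)
        assert dec.S == pytest.approx(s, abs=1e-12)
        assert dec.S_W == pytest.approx(s / 2, abs=1e-12)
        assert dec.S_B == pytest.approx(s / 2, abs=1e-12)

    def test_merging_identical_groups_preserves_S(self, scheme18):
        """Aggregation consistency: splitting one group into two identical
        halves leaves overall diversity unchanged."""
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(18))
        q = rng.dirichlet(np.ones(18))
        da = cd.CauseDistribution(scheme18, p)
        db = cd.CauseDistribution(scheme18, q)
        gm2 = cd.GroupedMortality(scheme18, ("a", "b"), np.array([0.4, 0.6]), (da, db))
        gm3 = cd.GroupedMortality(
            scheme18, ("a1", "a2", "b"), np.array([0.2, 0.2, 0.6]), (da, da, db)
        )
        assert cd.within_between(gm3).S == pytest.approx(cd.within_between(gm2).S, abs=1e-12)


class TestDiversityMatrix:
    def test_identical_groups_constant_matrix(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.6, 0.4]))
        gm = cd.GroupedMortality(scheme2, ("a", "b", "c"), np.full(3, 1 / 3), (d, d, d))
        M = cd.diversity_matrix(gm)
        np.testing.assert_allclose(M.values, cd.simpson(d), atol=1e-15)

    def test_disjoint_groups(self, scheme2):
        a = cd.CauseDistribution(scheme2, np.array([1.0, 0.0]))
        b = cd.CauseDistribution(scheme2, np.array([0.0, 1.0]))
        gm = cd.GroupedMortality(scheme2, ("a", "b"), np.array([0.5, 0.5]), (a, b))
        M = cd.diversity_matrix(gm).values
        np.testing.assert_array_equal(np.diag(M), [0.0, 0.0])
        assert M[0, 1] == 1.0

    def test_entries_match_scalar_recomputation(self):
        """21 random groups: every matrix entry equals the corresponding
        scalar simpson / pair-diversity evaluation."""
        rng = np.random.default_rng(21)
        gm = random_grouped(rng, G=21)
        M = cd.diversity_matrix(gm)
        assert M.group_labels == gm.group_labels
        for g in range(21):
            assert M.values[g, g] == pytest.approx(
                cd.simpson(gm.distributions[g]), abs=1e-12
            )
            for h in range(g + 1, 21):
                assert M.values[g, h] == pytest.approx(
                    cd.pair_diversity(gm.distributions[g], gm.distributions[h]),
                    abs=1e-12,
                )

    def test_quadratic_form_routes_agree(self, worked_gm):
        M = cd.diversity_matrix(worked_gm)
        s = cd.quadratic_form(worked_gm.weights, M)
        assert s == pytest.approx(4 / 9, abs=1e-12)

    def test_quadratic_form_constant_matrix_returns_constant(self):
        M = cd.DiversityMatrix(("a", "b", "c"), np.full((3, 3), 0.37))
        assert cd.quadratic_form(np.array([0.2, 0.3, 0.5]), M) == pytest.approx(0.37, abs=1e-15)

    def test_quadratic_form_dimension_mismatch(self, worked_gm):
        M = cd.diversity_matrix(worked_gm)
        with pytest.raises(cd.ValidationError):
            cd.quadratic_form(np.array([1.0]), M)


class TestContributions:
    def test_cause_contributions_worked(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.7, 0.3]))
        np.testing.assert_allclose(cd.cause_contributions(d), [0.21, 0.21], atol=1e-15)
        assert cd.cause_contributions(d).sum() == pytest.approx(cd.simpson(d), abs=1e-15)

    def test_zero_share_contributes_zero_and_half_is_max(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([1.0, 0.0]))
        np.testing.assert_array_equal(cd.cause_contributions(d), [0.0, 0.0])
        d5 = cd.CauseDistribution(scheme2, np.array([0.5, 0.5]))
        np.testing.assert_allclose(cd.cause_contributions(d5), [0.25, 0.25])

    def test_group_contributions_worked(self, worked_gm):
        C = cd.group_contributions(worked_gm)
        np.testing.assert_allclose(C, [1 / 6, 5 / 18], atol=1e-12)
        assert C.sum() == pytest.approx(4 / 9, abs=1e-12)

    def test_single_group_contribution_is_S(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.3, 0.7]))
        gm = cd.GroupedMortality(scheme2, ("g",), np.array([1.0]), (d,))
        np.testing.assert_allclose(cd.group_contributions(gm), [cd.simpson(d)], atol=1e-15)

    def test_joint_contributions_worked(self, worked_gm):
        """Hand-evaluated 2x2 cell contributions of the worked instance."""
        J = cd.joint_contributions(worked_gm)
        expected = np.array([[1 / 9, 1 / 9], [1 / 18, 1 / 6]])
        np.testing.assert_allclose(J, expected, atol=1e-12)
        np.testing.assert_allclose(J.sum(axis=0), cd.group_contributions(worked_gm), atol=1e-12)
        assert J.sum() == pytest.approx(4 / 9, abs=1e-12)

    def test_joint_single_group_reduces_to_cause_contributions(self, scheme2):
        d = cd.CauseDistribution(scheme2, np.array([0.3, 0.7]))
        gm = cd.GroupedMortality(scheme2, ("g",), np.array([1.0]), (d,))
        np.testing.assert_allclose(
            cd.joint_contributions(gm)[:, 0], cd.cause_contributions(d), atol=1e-15
        )

    def test_absent_cause_row_is_zero(self, scheme18):
        rng = np.random.default_rng(5)
        P = rng.dirichlet(np.ones(17), size=3)
        P = np.hstack([P, np.zeros((3, 1))])  # last cause absent everywhere
        gm = cd.GroupedMortality(
            scheme18, ("a", "b", "c"), np.full(3, 1 / 3),
            tuple(cd.CauseDistribution(scheme18, p) for p in P),
        )
        np.testing.assert_array_equal(cd.joint_contributions(gm)[-1], 0.0)

    def test_contribution_table_identities(self):
        rng = np.random.default_rng(9)
        gm = random_grouped(rng, G=6)
        tab = cd.contribution_table(gm)
        assert tab.S == pytest.approx(cd.simpson(cd.pooled_distribution(gm)), abs=1e-12)
        assert tab.cause_frame()["share_of_S"].sum() == pytest.approx(1.0, abs=1e-9)


class TestContributionCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cd.contribution_correlation(x, x) == pytest.approx(1.0)
        assert cd.contribution_correlation(x, -x) == pytest.approx(-1.0)

    def test_five_point_longhand_pearson(self):
        """Matches the textbook formula evaluated by hand."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert cd.contribution_correlation(x, y) == pytest.approx(expected, abs=1e-15)

    def test_zero_variance_rejected(self):
        with pytest.raises(cd.ValidationError, match="zero variance"):
            cd.contribution_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAlgebraicIdentities:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=150, deadline=None)
    def test_three_route_agreement(self, seed):
        """Pooled Simpson, within+between, summed group contributions and
        the quadratic form all give the same S; cell contributions sum to
        group contributions."""
        rng = np.random.default_rng(seed)
        gm = random_grouped(rng)
        s_pooled = cd.simpson(cd.pooled_distribution(gm))
        dec = cd.within_between(gm)
        s_quad = cd.quadratic_form(gm.weights, cd.diversity_matrix(gm))
        C = cd.group_contributions(gm)
        J = cd.joint_contributions(gm)
        assert abs(dec.S - s_pooled) <= 1e-12
        assert abs(C.sum() - s_pooled) <= 1e-12
        assert abs(s_quad - s_pooled) <= 1e-12
        np.testing.assert_allclose(J.sum(axis=0), C, atol=1e-12)
        assert 0.0 <= dec.S_W <= dec.S + 1e-12
        assert dec.S_B >= 0.0
        assert dec.S <= 17 / 18 + 1e-12

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, seed):
        """Relabeling causes and groups leaves S, S_W, S_B unchanged and
        permutes the contribution tables coherently."""
        rng = np.random.default_rng(seed)
        gm = random_grouped(rng, G=int(rng.integers(2, 8)))
        perm_c = rng.permutation(18)
        perm_g = rng.permutation(gm.G)
        scheme_p = cd.CauseScheme(tuple(gm.scheme.labels[i] for i in perm_c))
        gm_p = cd.GroupedMortality(
            scheme_p,
            tuple(gm.group_labels[g] for g in perm_g),
            gm.weights[perm_g],
            tuple(
                cd.CauseDistribution(scheme_p, gm.distributions[g].shares[perm_c],
                                     n=gm.distributions[g].n)
                for g in perm_g
            ),
        )
        dec, dec_p = cd.within_between(gm), cd.within_between(gm_p)
        assert dec_p.S == pytest.approx(dec.S, abs=1e-12)
        assert dec_p.S_W == pytest.approx(dec.S_W, abs=1e-12)
        assert dec_p.S_B == pytest.approx(dec.S_B, abs=1e-12)
        np.testing.assert_allclose(
            cd.group_contributions(gm_p), cd.group_contributions(gm)[perm_g], atol=1e-12
        )
        np.testing.assert_allclose(
            cd.joint_contributions(gm_p),
            cd.joint_contributions(gm)[perm_c][:, perm_g],
            atol=1e-12,
        )
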