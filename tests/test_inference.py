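import itertools

import numpy as np
import pytest
from scipy import stats

from snba.inference import (
    TestSpec,
    hotelling_f_test,
    subset_mean_test,
    t_test,
    wilcoxon_rank_test,
    z_test_diff,
)


def enumerate_wmw_p(g1, g2, alternative="greater"):
    """Exact WMW p-value by brute force over all group assignments.

    U counts pairs (x in group1, y in group2) with y > x; the one-sided
    'greater' p is the fraction of assignments with U at least as large
    as observed.
    """
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)

    def u_stat(idx1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx1)] = True
        x, y = pooled[mask], pooled[~mask]
        return np.sum(y[None, :] > x[:, None])

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)])
    if alternative == "greater":
        return np.mean(us >= u_obs)
    p_hi = np.mean(us >= u_obs)
    p_lo = np.mean(us <= u_obs)
    return min(1.0, 2 * min(p_hi, p_lo))


class TestZ:
    def test_identical_samples_give_half(self, rng):
        x = rng.normal(size=10)
        d, p = z_test_diff(x, x, sigma=1.0, alternative="greater")
        assert d == 0.0
        assert p == pytest.approx(0.5)

    def test_five_percent_at_the_normal_quantile(self):
        # D placed exactly at sigma*sqrt(2/n)*PhiInv(0.95) -> one-sided p = 0.05
        sigma, n = 1.3, 8
        shift = sigma * np.sqrt(2 / n) * stats.norm.ppf(0.95)
        x1 = np.zeros(n)
        x2 = np.zeros(n) + shift
        _, p = z_test_diff(x1, x2, sigma=sigma, alternative="greater")
        assert p == pytest.approx(0.05, abs=1e-12)
        _, p2 = z_test_diff(x1, x2, sigma=sigma, alternative="two-sided")
        assert p2 == pytest.approx(0.10, abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            z_test_diff([1.0], [2.0], sigma=0.0)


class TestSubsetMean:
    def test_null_diffs_give_half(self):
        _, p = subset_mean_test(np.zeros(5), sigma=1.0, n=10)
        assert p == pytest.approx(0.5)

    def test_single_atom_reduces_to_z_test(self, rng):
        n = 12
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        d = x2.mean() - x1.mean()
        dz, pz = z_test_diff(x1, x2, sigma=2.0, alternative="greater")
        dm, pm = subset_mean_test(np.array([d]), sigma=2.0, n=n, alternative="greater")
        assert dm == pytest.approx(dz)
        assert pm == pytest.approx(pz, abs=1e-12)

    def test_p_at_swa_critical_value_is_alpha_over_s(self):
        from snba.power import PowerSpec, critical_value_swa

        spec = PowerSpec(m=128, s=16, m_i=8, delta=1.0, sigma=1.5, n=20, alpha=0.05)
        c = critical_value_swa(spec)
        diffs = np.full(spec.m_i, c)  # subset mean exactly at the critical value
        _, p = subset_mean_test(diffs, sigma=spec.sigma, n=spec.n, alternative="greater")
        assert p == pytest.approx(spec.alpha / spec.s, rel=1e-9)

    def test_permutation_invariance(self, rng):
        diffs = rng.normal(size=9)
        _, p1 = subset_mean_test(diffs, sigma=1.0, n=5)
        _, p2 = subset_mean_test(rng.permutation(diffs), sigma=1.0, n=5)
        assert p1 == pytest.approx(p2)


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_test([1, 2], [3, 4], alternative="greater")
        assert p == pytest.approx(1 / 6)

    def test_equal_multisets_two_sided_p_one(self):
        _, p = wilcoxon_rank_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0], alternative="two-sided")
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        g1 = rng.normal(size=4)
        g2 = rng.normal(size=3) + 0.5
        _, p_fwd = wilcoxon_rank_test(g1, g2, alternative="greater")
        _, p_rev = wilcoxon_rank_test(g2, g1, alternative="greater")
        # discrete exact tails overlap at the observed point mass:
        # p_fwd + p_rev = 1 + P(U = u_obs)
        assert p_fwd + p_rev >= 1.0 - 1e-12
        assert enumerate_wmw_p(g2, g1, "greater") == pytest.approx(p_rev, abs=1e-12)
        _, p_two = wilcoxon_rank_test(g1, g2, alternative="two-sided")
        _, p_two_rev = wilcoxon_rank_test(g2, g1, alternative="two-sided")
        assert p_two == pytest.approx(p_two_rev)

    def test_degenerate_identical_values_warn_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = wilcoxon_rank_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_agrees_with_enumeration_all_small_splits(self, rng):
        """Exhaustive oracle: every rank arrangement for n1 + n2 <= 8."""
        for n1, n2 in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (2, 6)]:
            n = n1 + n2
            for comb in itertools.combinations(range(n), n1):
                ranks = np.arange(1.0, n + 1)
                g1 = ranks[list(comb)]
                g2 = np.delete(ranks, list(comb))
                _, p = wilcoxon_rank_test(g1, g2, alternative="greater")
                assert p == pytest.approx(
                    enumerate_wmw_p(g1, g2, "greater"), abs=1e-12
                ), (n1, n2, comb)


class TestHotelling:
    def test_p1_equals_squared_pooled_t(self, rng):
        for _ in range(20):
            s1 = rng.normal(size=(7, 1))
            s2 = rng.normal(size=(9, 1)) + 0.3
            f, p = hotelling_f_test(s1, s2)
            t, pt = stats.ttest_ind(s2[:, 0], s1[:, 0])
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-10)

    def test_zero_difference_gives_f_zero_p_one(self):
        base = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 1.5]])
        f, p = hotelling_f_test(base, base.copy())
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_dimension_precondition(self, rng):
        s1 = rng.normal(size=(3, 4))
        s2 = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="n1 \\+ n2 - 2 > p"):
            hotelling_f_test(s1, s2)

    def test_singular_covariance_advises(self, rng):
        col = rng.normal(size=(8, 1))
        s1 = np.hstack([col, col])  # perfectly collinear components
        s2 = np.hstack([col + 1, col + 1])
        with pytest.raises(np.linalg.LinAlgError, match="fewer summary components"):
            hotelling_f_test(s1, s2)


class TestNullUniformity:
    """Under simulated null data every test's p-values are ~ Uniform(0, 1)."""

    def test_z_and_subset_p_uniform(self):
        rng = np.random.default_rng(7)
        n, reps = 10, 10_000
        d = rng.standard_normal(reps) * np.sqrt(2 / n)
        p = stats.norm.sf(d / np.sqrt(2 / n))
        assert stats.kstest(p, "uniform").pvalue > 1e-3
        m_i = 6
        diffs = rng.standard_normal((reps, m_i)) * np.sqrt(2 / n)
        p_sub = stats.norm.sf(diffs.mean(axis=1) / np.sqrt(2 / (n * m_i)))
        assert stats.kstest(p_sub, "uniform").pvalue > 1e-3

    def test_t_p_uniform(self):
        rng = np.random.default_rng(8)
        x1 = rng.standard_normal((9, 10_000))
        x2 = rng.standard_normal((11, 10_000))
        p = stats.ttest_ind(x2, x1, axis=0).pvalue
        assert stats.kstest(p, "uniform").pvalue > 1e-3

    def test_wilcoxon_p_near_uniform(self):
        # discrete support: bound the KS distance instead of its p-value
        rng = np.random.default_rng(9)
        x1 = rng.standard_normal((20, 5000))
        x2 = rng.standard_normal((20, 5000))
        p = stats.mannwhitneyu(x2, x1, axis=0, alternative="two-sided",
                               method="asymptotic").pvalue
        assert stats.kstest(p, "uniform").statistic < 0.03

    def test_hotelling_p_uniform(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(2000):
            s1 = rng.standard_normal((8, 2))
            s2 = rng.standard_normal((8, 2))
            pvals.append(hotelling_f_test(s1, s2)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestSpecValidation:
    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            TestSpec(test="anova")

    def test_z_requires_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            TestSpec(test="z_known_sigma")

    def test_t_test_degenerate_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = t_test([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
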