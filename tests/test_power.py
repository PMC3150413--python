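import itertools

import numpy as np
import pytest
from scipy import stats

from snba.power import (
    PowerSpec,
    critical_value_awa,
    critical_value_swa,
    pi_star,
    power_awa,
    power_swa,
)


def spec(**kw):
    base = dict(m=128, s=16, m_i=8, delta=1.0, sigma=1.0, n=20, alpha=0.05, pi=0.5)
    base.update(kw)
    return PowerSpec(**base)


class TestCriticalValues:
    def test_single_test_is_plain_normal_quantile(self):
        s = spec(m=1, s=1, m_i=1, sigma=1.0, n=2)
        assert critical_value_awa(s) == pytest.approx(stats.norm.ppf(0.95), rel=1e-9)

    def test_awa_increasing_in_m(self):
        cs = [critical_value_awa(spec(m=m, s=1)) for m in (1, 10, 100, 10_000)]
        assert np.all(np.diff(cs) > 0)

    def test_scaling_in_sigma(self):
        assert critical_value_awa(spec(sigma=2.0)) == pytest.approx(
            2 * critical_value_awa(spec(sigma=1.0))
        )
        assert critical_value_swa(spec(sigma=2.0)) == pytest.approx(
            2 * critical_value_swa(spec(sigma=1.0))
        )

    def test_swa_reduces_to_awa_when_no_grouping(self):
        s = spec(m=64, s=64, m_i=1)
        assert critical_value_swa(s) == pytest.approx(critical_value_awa(s))

    def test_subset_size_four_halves_the_scale(self):
        c1 = critical_value_swa(spec(m_i=1))
        c4 = critical_value_swa(spec(m_i=4))
        assert c4 == pytest.approx(c1 / 2)

    def test_swa_combines_quantile_ratio_and_variance_reduction(self):
        # c_SWA = c_AWA * [PhiInv(1-a/s) / PhiInv(1-a/m)] / sqrt(m_i)
        s = spec(m=256, s=16, m_i=16)
        ratio = stats.norm.ppf(1 - s.alpha / s.s) / stats.norm.ppf(1 - s.alpha / s.m)
        assert critical_value_swa(s) == pytest.approx(
            critical_value_awa(s) * ratio / np.sqrt(s.m_i), rel=1e-12
        )
        assert critical_value_swa(s) < critical_value_awa(s)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(m=8, s=16, m_i=2, delta=1.0)  # s > m
        with pytest.raises(ValueError):
            PowerSpec(m=16, s=8, m_i=2, delta=1.0, alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(m=16, s=8, m_i=2, delta=1.0, pi=-0.1)


class TestPowerFunctions:
    def test_null_effect_gives_per_test_level(self):
        s = spec(delta=0.0)
        assert power_awa(s) == pytest.approx(s.alpha / s.m, rel=1e-9)
        assert power_swa(s.with_(pi=0.0)) == pytest.approx(s.alpha / s.s, rel=1e-9)

    def test_huge_effect_gives_power_one(self):
        assert power_awa(spec(delta=100.0)) == pytest.approx(1.0)
        assert power_swa(spec(delta=100.0, pi=1.0)) == pytest.approx(1.0)

    def test_swa_reduces_to_awa(self):
        s = spec(m=64, s=64, m_i=1, pi=1.0)
        assert power_swa(s) == pytest.approx(power_awa(s), rel=1e-12)

    def test_monotonicity_grid(self):
        base = spec(pi=0.5)
        assert power_swa(base.with_(pi=0.6)) > power_swa(base)
        assert power_swa(base.with_(m_i=16, m=256)) > power_swa(base)
        assert power_swa(base.with_(delta=1.5)) > power_swa(base)
        assert power_swa(base.with_(n=40)) > power_swa(base)
        assert power_swa(base.with_(sigma=2.0)) < power_swa(base)
        assert power_swa(base.with_(s=32)) < power_swa(base)

    def test_awa_matches_monte_carlo(self):
        # rejection rate of affected atoms at the Bonferroni critical value
        rng = np.random.default_rng(42)
        s = spec(m=64, s=8, m_i=8, delta=1.0, n=20, alpha=0.05)
        reps = 10_000
        sd = s.sigma * np.sqrt(2 / s.n)
        d = rng.standard_normal(reps) * sd + s.delta
        hit = np.mean(d > critical_value_awa(s))
        se = np.sqrt(hit * (1 - hit) / reps)
        assert abs(hit - power_awa(s)) < 3 * se + 1e-9

    def test_swa_matches_monte_carlo(self):
        rng = np.random.default_rng(43)
        s = spec(m=64, s=8, m_i=8, delta=1.0, n=20, pi=0.5)
        reps = 10_000
        sd = s.sigma * np.sqrt(2 / s.n)
        k = int(s.pi * s.m_i)
        shifts = np.r_[np.full(k, s.delta), np.zeros(s.m_i - k)]
        t = (rng.standard_normal((reps, s.m_i)) * sd + shifts).mean(axis=1)
        hit = np.mean(t > critical_value_swa(s))
        se = np.sqrt(hit * (1 - hit) / reps)
        assert abs(hit - power_swa(s)) < 3 * se + 1e-9


class TestPiStar:
    def test_no_grouping_crossover_at_one(self):
        s = spec(m=64, s=64, m_i=1)
        assert pi_star(s).value == pytest.approx(1.0, rel=1e-12)

    def test_defining_identity(self):
        for s in (spec(), spec(m=512, s=32, m_i=16, delta=2.0), spec(n=6, sigma=2.5)):
            ps = pi_star(s)
            assert power_swa(s.with_(pi=min(max(ps.value, 0), 1))) == pytest.approx(
                power_awa(s), abs=1e-12
            )

    def test_always_below_inverse_sqrt_subset_size(self):
        # exhaustive grid, > 1000 parameter combinations
        grid = itertools.product(
            (2, 4, 8, 16, 25),          # m_i
            (0.5, 1.0, 2.0, 4.0),       # delta
            (5, 20, 50),                # n
            (0.5, 1.0, 2.0),            # sigma
            (0.01, 0.05, 0.1),          # alpha
            (10, 50),                   # s
        )
        count = 0
        for m_i, delta, n, sigma, alpha, s_sub in grid:
            s = PowerSpec(m=s_sub * m_i, s=s_sub, m_i=m_i, delta=delta,
                          sigma=sigma, n=n, alpha=alpha)
            assert pi_star(s).value < 1 / np.sqrt(m_i) + 1e-12
            count += 1
        assert count >= 1000

    def test_subset_size_and_snr_monotonicity(self):
        # larger subsets lower the crossover; the SWA advantage grows
        # (pi* shrinks) when noise grows or the effect/sample size shrink
        s8 = spec(m=512, s=32, m_i=8)
        s16 = spec(m=512, s=32, m_i=16)
        assert pi_star(s16).value < pi_star(s8).value
        assert pi_star(s8.with_(sigma=2.0)).value < pi_star(s8).value
        assert pi_star(s8.with_(n=10)).value < pi_star(s8).value
        assert pi_star(s8.with_(delta=0.5)).value < pi_star(s8).value

    def test_out_of_range_flagged_not_clipped(self):
        # a tiny effect makes the crossover negative: the SWA dominates at
        # every proportion, and the raw value is reported with a flag
        ps = pi_star(spec(m=512, s=2, m_i=2, delta=0.01, n=2))
        assert not ps.in_range
        assert ps.value < 0.0

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            pi_star(spec(delta=0.0))
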