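"""Reservoir construction, the sigma_star <-> balance map, and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from rbnres.network import (
    InfeasibleDegreeError,
    ReservoirSpec,
    balance_of_sigma_star,
    balance_of_sigma_star_printed,
    build_reservoir,
    build_zero_balance_reservoir,
    load_reservoir,
    save_reservoir,
    sigma_star_of_balance,
    summarize_balance,
)
from conftest import toy_reservoir


class TestSpecValidation:
    def test_infeasible_degree(self):
        with pytest.raises(InfeasibleDegreeError):
            ReservoirSpec(N=4, K=4, sigma_star=1.0)

    def test_too_small(self):
        with pytest.raises(ValueError):
            ReservoirSpec(N=1, K=1, sigma_star=1.0)

    @pytest.mark.parametrize("bad", [0, -1])
    def test_nonpositive_degree(self, bad):
        with pytest.raises(ValueError):
            ReservoirSpec(N=10, K=bad, sigma_star=1.0)

    def test_zero_sigma_star(self):
        with pytest.raises(ValueError):
            ReservoirSpec(N=10, K=2, sigma_star=0.0)

    def test_out_of_range_sigma_star_warns(self):
        with pytest.warns(UserWarning):
            ReservoirSpec(N=10, K=2, sigma_star=1e4)

    def test_density(self):
        assert ReservoirSpec(N=10000, K=16, sigma_star=2.0).density == 16 / 10000


class TestBuild:
    def test_degree_exactness_and_no_self_loops(self):
        res = build_reservoir(ReservoirSpec(N=10, K=2, sigma_star=1.0, seed=7))
        assert res.sources.shape == (10, 2)
        for i in range(10):
            row = res.sources[i]
            assert len(set(row.tolist())) == 2
            assert i not in row
            assert np.all((row >= 0) & (row < 10))

    def test_deterministic_in_seed(self):
        spec = ReservoirSpec(N=50, K=5, sigma_star=-2.0, seed=3)
        a, b = build_reservoir(spec), build_reservoir(spec)
        assert np.array_equal(a.sources, b.sources)
        assert np.array_equal(a.weights, b.weights)
        c = build_reservoir(ReservoirSpec(N=50, K=5, sigma_star=-2.0, seed=4))
        assert not np.array_equal(a.weights, c.weights)

    @pytest.mark.parametrize("N,K", [(10, 2), (100, 16), (201, 7)])
    def test_partition_exactness(self, N, K):
        res = build_reservoir(ReservoirSpec(N=N, K=K, sigma_star=1.0))
        assert len(res.input_set) == N // 2
        assert len(res.readout_set) == N - N // 2
        assert not set(res.input_set) & set(res.readout_set)
        assert set(res.input_set) | set(res.readout_set) == set(range(N))

    def test_large_reservoir_degree_exactness(self):
        res = build_reservoir(ReservoirSpec(N=2000, K=16, sigma_star=2.0, seed=0))
        srt = np.sort(res.sources, axis=1)
        assert (srt[:, 1:] != srt[:, :-1]).all()  # distinct
        assert (res.sources != np.arange(2000)[:, None]).all()  # no self

    def test_weight_sign_follows_sigma_star(self):
        pos = build_reservoir(ReservoirSpec(N=100, K=4, sigma_star=0.01, seed=1))
        neg = build_reservoir(ReservoirSpec(N=100, K=4, sigma_star=-0.01, seed=1))
        assert (pos.weights > 0).all()
        assert (neg.weights < 0).all()


class TestBalanceMap:
    def test_saturates_near_zero_sigma(self):
        assert balance_of_sigma_star(0.01) == pytest.approx(1.0, abs=1e-6)
        assert balance_of_sigma_star(-0.01) == pytest.approx(-1.0, abs=1e-6)

    def test_vanishes_at_large_sigma(self):
        assert abs(balance_of_sigma_star(1000)) < 1e-3
        assert abs(balance_of_sigma_star(-1000)) < 1e-3

    def test_interval_anchor(self):
        # sigma_star = -10 pairs with a balance of about -0.08
        b = balance_of_sigma_star(-10)
        assert b == pytest.approx(-(2 * ndtr(0.1) - 1), abs=1e-12)
        assert b == pytest.approx(-0.08, abs=0.005)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            balance_of_sigma_star(0.0)
        with pytest.raises(ValueError):
            balance_of_sigma_star_printed(0.0)

    @settings(deadline=None)
    @given(st.floats(min_value=1e-2, max_value=1e3))
    def test_sign_antisymmetry(self, s):
        assert balance_of_sigma_star(-s) == -balance_of_sigma_star(s)

    def test_strictly_decreasing_in_magnitude(self):
        # below |sigma_star| ~ 0.2 the balance saturates at 1.0 in float64
        mags = np.logspace(-0.5, 3, 40)
        b = balance_of_sigma_star(mags)
        assert (np.diff(b) < 0).all()

    @settings(deadline=None)
    @given(st.floats(min_value=0.3, max_value=1e3),
           st.sampled_from([-1.0, 1.0]))
    def test_inverse_roundtrip(self, mag, sign):
        # restricted to the float64-invertible range (no saturation at b=1)
        s = sign * mag
        assert sigma_star_of_balance(balance_of_sigma_star(s)) == pytest.approx(
            s, rel=1e-6)

    def test_monte_carlo_sign_fraction_oracle(self):
        # fraction of positive draws from N(1, 2) over 1e6 samples
        rng = np.random.default_rng(12345)
        draws = rng.normal(1.0, 2.0, size=10**6)
        p_hat = (draws > 0).mean()
        b_hat = 2 * p_hat - 1
        se = 2 * np.sqrt(p_hat * (1 - p_hat) / 10**6)
        assert abs(b_hat - balance_of_sigma_star(2.0)) < 4 * se


class TestBalanceSummary:
    def test_all_positive_weights(self):
        res = toy_reservoir([[1], [0]], [[0.5], [2.0]])
        assert summarize_balance(res).b_empirical == 1.0

    def test_toy_counting(self):
        # weight multiset {+1, -1, +2, -3}: S=4, S+=2, S-=2, b=0
        res = toy_reservoir([[1], [2], [3], [0]],
                            [[1.0], [-1.0], [2.0], [-3.0]])
        s = summarize_balance(res)
        assert (s.S, s.S_plus, s.S_minus, s.b_empirical) == (4, 2, 2, 0.0)

    def test_exact_zero_weight_counts_in_S_only(self):
        res = toy_reservoir([[1], [2], [3], [0]],
                            [[0.0], [-1.0], [2.0], [-3.0]])
        s = summarize_balance(res)
        assert s.S == 4 and s.S_plus == 1 and s.S_minus == 2

    def test_empirical_matches_analytic_within_binomial_se(self):
        res = build_reservoir(ReservoirSpec(N=1000, K=4, sigma_star=-2.0, seed=9))
        s = summarize_balance(res)
        se = np.sqrt((1 - s.b_analytic**2) / s.S)
        assert abs(s.b_empirical - s.b_analytic) < 4 * se

    def test_mean_balance_over_seeds(self):
        # 200 seeds at (N=500, K=4, sigma_star=3): ensemble mean within
        # 2 standard errors of the mean of the analytic balance
        b_emp = np.array([
            summarize_balance(
                build_reservoir(ReservoirSpec(N=500, K=4, sigma_star=3.0, seed=s))
            ).b_empirical
            for s in range(200)
        ])
        target = balance_of_sigma_star(3.0)
        sem = b_emp.std(ddof=1) / np.sqrt(len(b_emp))
        assert abs(b_emp.mean() - target) < 2 * sem


class TestZeroBalance:
    def test_exact_zero(self):
        res = build_zero_balance_reservoir(
            ReservoirSpec(N=100, K=4, sigma_star=1e3, seed=2))
        assert summarize_balance(res).b_empirical == 0.0

    def test_odd_synapse_count_rejected(self):
        with pytest.raises(ValueError):
            build_zero_balance_reservoir(ReservoirSpec(N=3, K=1, sigma_star=10.0))


def test_serialization_roundtrip(tmp_path):
    res = build_reservoir(ReservoirSpec(N=30, K=3, sigma_star=-0.7, seed=11))
    prefix = tmp_path / "res"
    save_reservoir(res, prefix)
    back = load_reservoir(prefix)
    assert back.spec == res.spec
    assert np.array_equal(back.sources, res.sources)
    assert np.array_equal(back.weights, res.weights)  # bit-exact
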