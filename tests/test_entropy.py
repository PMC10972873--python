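"""BiEntropy, steady-window binarization, and variance-region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbnres.dynamics import ActivityTrace
from rbnres.entropy import (
    EntropyEnsemble,
    bientropy,
    binarize_steady,
    ensemble_entropy,
    find_variance_regions,
)


def trace_from_values(vals, N=10):
    counts = np.rint(np.asarray(vals) * N).astype(np.int64)
    return ActivityTrace(counts=counts, N=N)


class TestBinarize:
    def test_constant_signal_all_zero(self):
        bits = binarize_steady(trace_from_values([0.3] * 8), t0=0)
        assert bits.tolist() == [0] * 8

    def test_alternating(self):
        bits = binarize_steady(trace_from_values([0.2, 0.4, 0.2, 0.4]), t0=0)
        assert bits.tolist() == [0, 1, 0, 1]

    def test_additive_constant_invariance(self):
        a = trace_from_values([0.2, 0.4, 0.3, 0.4, 0.2, 0.1])
        shifted = ActivityTrace(counts=a.counts + 3, N=10)
        assert np.array_equal(binarize_steady(a, t0=0),
                              binarize_steady(shifted, t0=0))

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            binarize_steady(trace_from_values([0.1] * 10), t0=7)

    def test_default_window(self):
        tr = trace_from_values(np.linspace(0, 1, 2000))
        assert binarize_steady(tr).size == 1000


class TestBiEntropy:
    def test_all_zeros(self):
        assert bientropy([0] * 10) == 0.0

    def test_all_ones(self):
        assert bientropy([1] * 10) == 0.0

    def test_golden_0101_power(self):
        assert bientropy([0, 1, 0, 1], "power") == pytest.approx(1 / 7, abs=1e-12)

    def test_golden_1011_power(self):
        assert bientropy([1, 0, 1, 1], "power") == pytest.approx(0.94970, abs=1e-4)

    def test_too_short(self):
        with pytest.raises(ValueError):
            bientropy([0, 1, 0])

    def test_non_binary_content(self):
        with pytest.raises(ValueError):
            bientropy([0, 1, 2, 1])

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            bientropy([0, 1, 1, 0], variant="cubic")

    @pytest.mark.parametrize("variant", ["power", "logarithmic"])
    def test_bounds_on_random_strings(self, variant):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            bits = rng.integers(0, 2, size=rng.integers(4, 24))
            h = bientropy(bits, variant)
            assert 0.0 <= h <= 1.0

    def test_long_random_strings_near_one(self):
        # the logarithmic variant approaches 1 on long irregular strings; the
        # power variant cannot (half its weight sits on the 2-bit final
        # derivative, whose entropy vanishes with probability 1/2), which is
        # why it is not the default for 1000-bit steady windows
        rng = np.random.default_rng(1)
        strings = [rng.integers(0, 2, size=1000) for _ in range(50)]
        mean_log = np.mean([bientropy(s, "logarithmic") for s in strings])
        mean_pow = np.mean([bientropy(s, "power") for s in strings])
        assert mean_log > 0.95
        assert 0.0 < mean_pow < mean_log

    def test_power_variant_length_invariant_overflow(self):
        # normalised 2^k weights must not overflow for long strings
        h = bientropy(np.arange(4000) % 2 == 0, "power")
        assert np.isfinite(h)


class TestEnsemble:
    def test_two_point(self):
        assert ensemble_entropy([0.0, 1.0]) == (0.5, 0.25)

    def test_identical_values(self):
        assert ensemble_entropy([0.5] * 7)[1] == 0.0
        assert ensemble_entropy([0.4] * 7)[1] == pytest.approx(0.0, abs=1e-30)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_entropy([])

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(3)
        v = rng.random(100)
        mean, var = ensemble_entropy(v)
        ref_mean = sum(v) / len(v)
        ref_var = sum((x - ref_mean) ** 2 for x in v) / len(v)
        assert mean == pytest.approx(ref_mean, abs=1e-12)
        assert var == pytest.approx(ref_var, abs=1e-12)

    @settings(deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_population_normalization_identity(self, values):
        mean, var = ensemble_entropy(values)
        ssd = sum((x - mean) ** 2 for x in values)
        assert var * len(values) == pytest.approx(ssd, abs=1e-12)

    def test_ensemble_container(self):
        ens = EntropyEnsemble.from_values((100, 4, 2.0, 0.5), [0.2, 0.4, 0.6])
        assert ens.R == 3
        assert ens.mean == pytest.approx(0.4)


class TestVarianceRegions:
    def test_single_point_interval(self):
        reg = find_variance_regions([0.01, 0.1, 1.0], [0, 2e-4, 5e-5],
                                    threshold=1e-4)
        assert reg.intervals == ((1, 2, "critical"),)

    def test_all_below_threshold(self):
        reg = find_variance_regions([0.01, 0.1, 1.0], [0, 5e-5, 9e-5])
        assert reg.intervals == ()

    def test_two_bumps_critical_then_reentrant(self):
        # sigma_star axis: ordered phase at small |sigma_star|
        axis = -np.logspace(-2, 3, 8)  # negative sign, ascending magnitude
        var = [0, 3e-4, 4e-4, 0, 0, 2e-4, 3e-4, 0]
        reg = find_variance_regions(axis, var)
        assert reg.intervals == ((1, 3, "critical"), (5, 7, "re-entrant"))

    def test_b_axis_orientation(self):
        # b axis ascending in magnitude: ordered phase at *large* |b|, so the
        # outermost bump is critical even though it comes last in the array
        axis = [0.05, 0.2, 0.5, 0.9]
        var = [2e-4, 0, 0, 3e-4]
        reg = find_variance_regions(axis, var, axis="b")
        labels = {iv[:2]: iv[2] for iv in reg.intervals}
        assert labels[(3, 4)] == "critical"
        assert labels[(0, 1)] == "re-entrant"

    def test_unsorted_axis_rejected(self):
        with pytest.raises(ValueError):
            find_variance_regions([0.1, 1.0, 0.5], [0, 0, 0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            find_variance_regions([0.1, 1.0], [0.0])
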