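"""Time-domain entropy/complexity estimators: worked examples, closed
forms, invariances, and spot checks against the brute-force oracles (the
full oracle batteries run in the acceptance suite)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qeeg.features import (
    BinarySequence, DiscreteDistribution, FeatureParams, amplitude_histogram,
    binarize_mean, estimate_density, extract_all_features, higuchi_fd,
    lz76_complexity, lzc_normalized, permutation_entropy, renyi_entropy,
    sample_entropy, silverman_bandwidth, tsallis_entropy,
)
from qeeg.io import EEGRecording, Segment
from .oracles import (
    higuchi_fd_naive, lz76_naive, permutation_entropy_naive,
    renyi_entropy_naive, sample_entropy_naive,
)


class TestPermutationEntropy:
    def test_monotone_series_has_single_pattern(self):
        assert permutation_entropy(np.arange(100.0)) == pytest.approx(0.0)

    def test_near_uniform_patterns_approach_ln_6(self):
        # a long random permutation visits the 6 ordinal patterns of D=3
        # almost equally often, so PE approaches the ln 6 maximum
        rng = np.random.default_rng(0)
        x = rng.permutation(np.arange(720.0))
        pe = permutation_entropy(x)
        assert pe <= math.log(6) + 1e-12
        assert pe > 0.98 * math.log(6)  # random data near-uniform patterns

    def test_worked_seven_point_series(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        assert permutation_entropy(x, 3, 1) == pytest.approx(
            permutation_entropy_naive(x, 3, 1), abs=1e-12
        )

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(400)
        assert permutation_entropy(x) == pytest.approx(
            permutation_entropy(x + 57.0), abs=1e-12
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.array([1.0, 2.0]), D=3)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(1, 3))
    def test_bounded_by_ln_factorial_D(self, seed, D, tau):
        x = np.random.default_rng(seed).standard_normal(80)
        pe = permutation_entropy(x, D, tau)
        assert 0.0 <= pe <= math.log(math.factorial(D)) + 1e-12


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(50, 3.3)) == 0.0

    def test_periodic_worked_example(self):
        x = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3, 1])
        assert sample_entropy(x, m=2, r=0.5) == pytest.approx(
            sample_entropy_naive(x, 2, 0.5), abs=1e-12
        )

    def test_white_noise_matches_naive_oracle(self, rng):
        x = rng.standard_normal(2000)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(
            sample_entropy_naive(x, 2, r), rel=1e-12
        )

    def test_no_m_matches_is_undefined(self):
        # widely spaced points: no m-template pair within tolerance
        x = np.array([0.0, 100.0, -100.0, 200.0, -200.0, 400.0])
        with pytest.raises(ValueError):
            sample_entropy(x, m=2, r=0.5)

    def test_determinism(self, rng):
        x = rng.standard_normal(500)
        assert sample_entropy(x) == sample_entropy(x.copy())


class TestAmplitudeDensity:
    def test_recovers_standard_normal_density(self, rng):
        x = rng.standard_normal(10_000)
        d = estimate_density(x)
        phi = np.exp(-0.5 * d.grid ** 2) / np.sqrt(2 * np.pi)
        assert np.abs(d.f - phi).max() < 0.02

    def test_integrates_to_one(self, rng):
        d = estimate_density(rng.standard_normal(2000))
        assert np.trapezoid(d.f, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_change_of_variables_scaling(self, rng):
        x = rng.standard_normal(5000)
        d1, d10 = estimate_density(x), estimate_density(10 * x)
        assert np.ptp(d10.grid) == pytest.approx(10 * np.ptp(d1.grid), rel=0.01)
        assert d10.f.max() == pytest.approx(d1.f.max() / 10, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.full(100, 1.0))


class TestRenyiEntropy:
    def test_gaussian_closed_form(self, rng):
        sigma = 2.0
        x = sigma * rng.standard_normal(10_000)
        h = renyi_entropy(estimate_density(x), alpha=2)
        assert h == pytest.approx(math.log(2 * sigma * math.sqrt(math.pi)), rel=0.03)

    def test_uniform_closed_form(self, rng):
        w = 4.0
        x = rng.uniform(0, w, 20_000)
        h = renyi_entropy(estimate_density(x), alpha=2)
        assert h == pytest.approx(math.log(w), abs=0.08)  # KDE edge bias

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(2000)
        h1 = renyi_entropy(estimate_density(x))
        h2 = renyi_entropy(estimate_density(x + 1000.0))
        assert h1 == pytest.approx(h2, abs=1e-6)

    def test_scaling_shifts_by_ln_c(self, rng):
        x = rng.standard_normal(5000)
        h1 = renyi_entropy(estimate_density(x))
        hc = renyi_entropy(estimate_density(3.0 * x))
        assert hc - h1 == pytest.approx(math.log(3.0), abs=0.01)

    def test_matches_dense_integration_oracle(self, rng):
        x = rng.standard_normal(300)
        d = estimate_density(x)
        expected = renyi_entropy_naive(x, d.grid, silverman_bandwidth(x), 2.0)
        assert renyi_entropy(d, 2.0) == pytest.approx(expected, rel=1e-9)

    def test_alpha_one_rejected(self, rng):
        with pytest.raises(ValueError):
            renyi_entropy(estimate_density(rng.standard_normal(100)), alpha=1.0)


class TestTsallisEntropy:
    def test_uniform_four_bins_is_exactly_one(self):
        assert tsallis_entropy(DiscreteDistribution(np.full(4, 0.25)), 1.5) == 1.0

    def test_degenerate_distribution_is_zero(self):
        p = np.zeros(10)
        p[0] = 1.0
        assert tsallis_entropy(DiscreteDistribution(p), 1.5) == pytest.approx(0.0)

    def test_saturates_below_two_for_flat_distributions(self):
        values = [
            tsallis_entropy(DiscreteDistribution(np.full(n, 1.0 / n)), 1.5)
            for n in (10, 100, 1000, 10_000)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] < 2.0
        assert values[-1] > 1.97

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            DiscreteDistribution(np.array([0.7, 0.7]))


class TestAmplitudeHistogram:
    def test_constant_series_single_occupied_bin(self):
        p = amplitude_histogram(np.full(10, 2.0))
        assert p.probs.max() == 1.0

    def test_uniform_draws_near_uniform_probabilities(self, rng):
        p = amplitude_histogram(rng.uniform(0, 1, 1000), n_bins=10)
        assert np.abs(p.probs - 0.1).max() < 0.05

    def test_probabilities_sum_to_one(self, rng):
        p = amplitude_histogram(rng.standard_normal(500))
        assert p.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestHiguchiFd:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self, rng):
        assert higuchi_fd(rng.standard_normal(10_000)) == pytest.approx(2.0, abs=0.1)

    def test_dense_sinusoid_dimension_one(self):
        t = np.linspace(0, 2, 2000)
        assert higuchi_fd(np.sin(2 * np.pi * 3 * t)) == pytest.approx(1.0, abs=0.1)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(400)
        assert higuchi_fd(x, 8) == pytest.approx(higuchi_fd_naive(x, 8), rel=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(50.0), k_max=10)


class TestBinarization:
    @pytest.mark.parametrize("x, expected", [
        ([1, 3, 1, 3], [0, 1, 0, 1]),
        ([5, 5, 5], [0, 0, 0]),
        ([0, 10, 0, 0], [0, 1, 0, 0]),
    ])
    def test_mean_threshold_examples(self, x, expected):
        b = binarize_mean(np.array(x, float))
        assert b.bits.tolist() == expected


class TestLz76:
    def test_canonical_twelve_bit_example(self):
        b = np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 1, 1, 0], np.uint8)
        assert lz76_complexity(b) == 6

    @pytest.mark.parametrize("bits, expected", [
        ([0], 1),
        ([0, 1], 2),
        ([0, 1] * 6, 3),  # 0 | 1 | 0101010101
    ])
    def test_base_cases_and_alternation(self, bits, expected):
        assert lz76_complexity(np.array(bits, np.uint8)) == expected

    def test_constant_sequence_is_two_words(self):
        for n in (2, 5, 100):
            assert lz76_complexity(np.zeros(n, np.uint8)) == 2

    def test_normalized_value_of_worked_example(self):
        b = BinarySequence(np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 1, 1, 0]), 0.0)
        assert lzc_normalized(b) == pytest.approx(6 * math.log2(12) / 12, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
           st.lists(st.integers(0, 1), min_size=0, max_size=20))
    def test_monotone_under_extension_and_matches_oracle(self, bits, extra):
        b = np.array(bits, np.uint8)
        assert lz76_complexity(b) == lz76_naive(bits)
        longer = np.array(bits + extra, np.uint8)
        assert lz76_complexity(longer) >= lz76_complexity(b)


class TestExtractAllFeatures:
    def _segment(self, data, fs=250.0):
        rec = EEGRecording("p", "TD", fs,
                           [f"c{i}" for i in range(len(data))], data)
        return Segment(rec, 0, data.shape[1])

    def test_shape_and_finiteness(self, rng):
        seg = self._segment(rng.standard_normal((3, 2500)))
        df = extract_all_features(seg)
        assert len(df) == 3
        cols = [c for c in df.columns if c != "channel"]
        assert len(cols) == 9  # 8 features + normalized LZC
        assert np.isfinite(df[cols].to_numpy()).all()

    def test_duplicated_channel_gives_identical_rows(self, rng):
        x = rng.standard_normal(2500)
        df = extract_all_features(self._segment(np.vstack([x, x])))
        a, b = df.drop(columns="channel").iloc[0], df.drop(columns="channel").iloc[1]
        assert (a == b).all()

    def test_alpha_tone_raises_alpha_power_and_lowers_spectral_entropy(self, rng):
        noise = rng.standard_normal(2500)
        t = np.arange(2500) / 250.0
        tone = noise + 3 * np.sin(2 * np.pi * 10 * t)
        df = extract_all_features(self._segment(np.vstack([noise, tone])))
        assert df["spectral_entropy"][1] < df["spectral_entropy"][0]
        from qeeg.spectral import compute_psd, relative_band_power
        alpha_noise = relative_band_power(compute_psd(noise, 250.0))[2]
        alpha_tone = relative_band_power(compute_psd(tone, 250.0))[2]
        assert alpha_tone > alpha_noise

    def test_failure_tagged_with_channel(self):
        data = np.vstack([np.random.default_rng(0).standard_normal(2500),
                          np.zeros(2500)])
        from qeeg.features import FeatureExtractionError
        with pytest.raises(FeatureExtractionError) as err:
            extract_all_features(self._segment(data))
        assert err.value.channel == "c1"
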