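"""Symlet-4 DWT cascade, thresholding rules, and the denoising pipeline."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcgscreen import (
    PcgSignal,
    WaveletSpec,
    add_noise,
    decompose,
    denoise,
    dwt_single,
    generate_pcg,
    idwt_single,
    mad_sigma,
    preset,
    reconstruct,
    soft_threshold,
    threshold_decomposition,
    universal_threshold,
)

from _oracles import periodized_analysis_matrix, snr_db


class TestWaveletSpec:
    def test_sym4_filters_validate(self):
        spec = WaveletSpec("sym4")
        assert spec.filter_length == 8
        assert spec.dec_lo.sum() == pytest.approx(np.sqrt(2), abs=1e-10)

    def test_corrupted_filters_rejected(self):
        good = WaveletSpec("sym4")
        bad = good.dec_lo.copy()
        bad[0] += 1e-3
        with pytest.raises(ValueError):
            WaveletSpec("bad", bad, good.dec_hi, good.rec_lo, good.rec_hi)


class TestSingleLevel:
    def test_constant_signal(self):
        c = 0.7
        cA, cD = dwt_single(np.full(8, c))
        np.testing.assert_allclose(cA, c * np.sqrt(2), atol=1e-10)
        np.testing.assert_allclose(cD, 0, atol=1e-10)

    def test_zero_signal(self):
        cA, cD = dwt_single(np.zeros(16))
        assert not cA.any() and not cD.any()

    @pytest.mark.parametrize("n", [8, 12, 16, 24, 32])
    def test_matches_explicit_matrix_oracle(self, n, rng):
        x = rng.normal(size=n)
        M = periodized_analysis_matrix(n)
        # The oracle matrix must itself be orthogonal.
        np.testing.assert_allclose(M @ M.T, np.eye(n), atol=1e-10)
        cA, cD = dwt_single(x)
        ref = M @ x
        np.testing.assert_allclose(cA, ref[: n // 2], atol=1e-10)
        np.testing.assert_allclose(cD, ref[n // 2:], atol=1e-10)

    def test_round_trip(self, rng):
        x = rng.normal(size=16)
        cA, cD = dwt_single(x)
        np.testing.assert_allclose(idwt_single(cA, cD), x, atol=1e-10)

    def test_zero_coefficients_give_zero_signal(self):
        np.testing.assert_array_equal(idwt_single(np.zeros(8), np.zeros(8)),
                                      np.zeros(16))

    def test_errors(self):
        with pytest.raises(ValueError):
            dwt_single([])
        with pytest.raises(ValueError):
            dwt_single(np.zeros(7))  # odd length under periodization
        with pytest.raises(ValueError):
            dwt_single(np.zeros(8), mode="not-a-mode")
        with pytest.raises(ValueError):
            idwt_single(np.zeros(4), np.zeros(5))


class TestMultilevel:
    def test_level_one_equals_single_step(self, rng):
        x = rng.normal(size=32)
        sig = PcgSignal(x, fs=2000.0)
        d = decompose(sig, level=1)
        cA, cD = dwt_single(x)
        np.testing.assert_array_equal(d.cA, cA)
        np.testing.assert_array_equal(d.cD[0], cD)

    def test_cascade_lengths(self, rng):
        sig = PcgSignal(rng.normal(size=64), fs=2000.0)
        d = decompose(sig, level=4)
        assert [c.size for c in d.cD] == [4, 8, 16, 32]
        assert d.cA.size == 4
        assert d.level == 4 and d.n_original == 64

    @pytest.mark.parametrize("n", [16, 50, 64, 100, 257, 1024])
    def test_round_trip_arbitrary_lengths(self, n, rng):
        x = rng.normal(size=n)
        sig = PcgSignal(x, fs=2000.0)
        back = reconstruct(decompose(sig, level=4))
        assert back.n == n
        np.testing.assert_allclose(back.samples, x, atol=1e-9)

    def test_parseval(self, rng):
        x = rng.normal(size=256)
        d = decompose(PcgSignal(x, fs=2000.0), level=4)
        coeff_energy = sum(float(np.sum(c ** 2)) for c in d.coeff_arrays())
        assert coeff_energy == pytest.approx(float(np.sum(x ** 2)), abs=1e-9)

    def test_level_too_deep(self):
        with pytest.raises(ValueError):
            decompose(PcgSignal(np.zeros(8), fs=100.0), level=4)

    def test_constant_survives_detail_zeroing(self):
        sig = PcgSignal(np.full(64, 0.3), fs=2000.0)
        d = decompose(sig, level=4)
        d = dataclasses.replace(d, cD=[np.zeros_like(c) for c in d.cD])
        np.testing.assert_allclose(reconstruct(d).samples, 0.3, atol=1e-9)

    def test_alternating_signal_lives_in_details(self):
        # A +1/-1 alternation is (almost) pure highpass content: zeroing the
        # approximation must retain >= 99% of its energy.
        x = np.tile([1.0, -1.0], 64)
        sig = PcgSignal(x, fs=2000.0)
        d = decompose(sig, level=4)
        d = dataclasses.replace(d, cA=np.zeros_like(d.cA))
        kept = float(np.sum(reconstruct(d).samples ** 2))
        assert kept >= 0.99 * float(np.sum(x ** 2))

    def test_inconsistent_lengths_rejected(self, rng):
        d = decompose(PcgSignal(rng.normal(size=64), fs=2000.0), level=4)
        d = dataclasses.replace(d, cD=[d.cD[0][:2], *d.cD[1:]])
        with pytest.raises(ValueError):
            reconstruct(d)


class TestThresholdRules:
    def test_mad_definition(self):
        assert mad_sigma([0.6745]) == pytest.approx(1.0, rel=1e-4)
        assert mad_sigma(np.zeros(10)) == 0.0
        with pytest.raises(ValueError):
            mad_sigma([])

    def test_mad_estimates_gaussian_scale(self, rng):
        draws = rng.normal(0, 2.0, 100_000)
        assert mad_sigma(draws) == pytest.approx(2.0, rel=0.02)

    def test_universal_threshold_closed_form(self):
        assert universal_threshold(5.0, 1) == 0.0
        assert universal_threshold(0.0, 1000) == 0.0
        n = round(np.e ** 2)
        assert universal_threshold(1.0, n) == pytest.approx(
            np.sqrt(2 * np.log(n)), abs=1e-12)
        with pytest.raises(ValueError):
            universal_threshold(1.0, 0)

    def test_soft_threshold_formula(self):
        np.testing.assert_allclose(
            soft_threshold([1.0, -0.5, 0.2], 0.3), [0.7, -0.2, 0.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30),
           st.floats(0, 5))
    def test_soft_threshold_properties(self, xs, t):
        x = np.array(xs)
        y = soft_threshold(x, t)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-15)       # shrinkage
        assert np.all(np.abs(y) <= np.maximum(np.abs(x) - t, 0) + 1e-12)
        if t == 0:
            np.testing.assert_array_equal(y, x)
        if x.size and t >= np.max(np.abs(x)):
            assert not y.any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold([1.0], -0.1)

    def test_approximation_never_thresholded(self, rng):
        d = decompose(PcgSignal(rng.normal(size=128), fs=2000.0), level=3)
        for scope in ("per_level", "global"):
            shrunk = threshold_decomposition(d, scope)
            np.testing.assert_array_equal(shrunk.cA, d.cA)
            for orig, new in zip(d.cD, shrunk.cD):
                assert np.all(np.abs(new) <= np.abs(orig) + 1e-15)


class TestDenoise:
    def test_zero_signal_unchanged(self):
        sig = PcgSignal(np.zeros(64), fs=2000.0)
        np.testing.assert_array_equal(denoise(sig).samples, sig.samples)

    def test_constant_signal_unchanged(self):
        sig = PcgSignal(np.full(64, 0.4), fs=2000.0)
        np.testing.assert_allclose(denoise(sig).samples, 0.4, atol=1e-9)

    def test_output_length_equals_input_length(self, rng):
        sig = PcgSignal(rng.normal(size=777), fs=2000.0)
        assert denoise(sig).n == 777

    @pytest.mark.parametrize("scope", ["per_level", "global"])
    def test_improves_snr_on_noisy_pcg(self, scope):
        params = dataclasses.replace(preset("healthy"), noise_sd=0.0,
                                     duration=5.0)
        clean = generate_pcg(params)
        noisy = add_noise(clean, 0.05, seed=1)
        out = denoise(noisy, threshold_scope=scope)
        assert snr_db(clean.samples, out.samples) > \
            snr_db(clean.samples, noisy.samples)

    def test_norm_non_expansion(self, rng):
        for _ in range(50):
            n = int(rng.integers(16, 300))
            sig = PcgSignal(rng.normal(size=n), fs=2000.0)
            assert np.linalg.norm(denoise(sig).samples) <= \
                np.linalg.norm(sig.samples) + 1e-9
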