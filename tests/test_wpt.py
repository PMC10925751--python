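import math

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from headwave import (AccelSignal, QMFPair, band_range, build_sym2,
                      frequency_order, wp_coefficients, wp_decompose)


def _signal(values, fs=5000.0):
    return AccelSignal(np.asarray(values, float), dt=1.0 / fs)


class TestSym2Filters:
    def test_taps_match_reference_library(self):
        pair = build_sym2()
        ref = pywt.Wavelet("sym2")
        np.testing.assert_allclose(pair.h, ref.dec_lo, atol=1e-12)
        np.testing.assert_allclose(pair.g, ref.dec_hi, atol=1e-12)

    def test_orthonormal_identities(self):
        pair = build_sym2()
        assert abs(pair.h.sum() - math.sqrt(2)) < 1e-12
        assert abs((pair.h ** 2).sum() - 1.0) < 1e-12
        assert abs((pair.g ** 2).sum() - 1.0) < 1e-12
        assert abs(np.dot(pair.h, pair.g)) < 1e-12

    def test_two_scale_relation_up_to_even_shift_and_sign(self):
        # g_k = (-1)^k h_{1-k} taken modulo the support defines g up to an
        # even circular shift and a global sign; the shipped pair is in
        # that family.
        pair = build_sym2()
        L = pair.h.size
        base = np.array([(-1.0) ** k * pair.h[(1 - k) % L] for k in range(L)])
        candidates = [s * np.roll(base, r) for s in (1.0, -1.0) for r in range(0, L, 2)]
        assert any(np.allclose(pair.g, c, atol=1e-12) for c in candidates)

    def test_invalid_taps_rejected(self):
        with pytest.raises(ValueError):
            QMFPair(h=np.array([0.5, 0.5, 0.5, 0.5]), g=np.array([0.5, -0.5, 0.5, -0.5]))


class TestDecomposition:
    def test_level_zero_is_identity_energy(self, rng):
        x = rng.normal(size=512)
        spec = wp_decompose(_signal(x), levels=0)
        assert spec.energies.size == 1
        assert spec.energies[0] == pytest.approx(np.sum(x ** 2), rel=1e-12)

    def test_unit_impulse_total_energy(self):
        x = np.zeros(512)
        x[100] = 1.0
        for levels in (1, 5, 9):
            spec = wp_decompose(_signal(x), levels=levels)
            assert spec.total_energy == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("length,levels", [(512, 1), (512, 5), (1024, 2), (4096, 9)])
    def test_terminal_coefficients_match_pywt(self, rng, length, levels):
        x = rng.normal(size=length)
        mine = wp_coefficients(x, levels)
        wp = pywt.WaveletPacket(x, "sym2", mode="periodization", maxlevel=levels)
        ref = [node.data for node in wp.get_level(levels, order="natural")]
        err = max(np.max(np.abs(a - b)) for a, b in zip(mine, ref))
        assert err < 1e-10

    def test_frequency_ordering_matches_pywt(self, rng):
        x = rng.normal(size=1024)
        levels = 5
        spec = wp_decompose(_signal(x), levels=levels)
        wp = pywt.WaveletPacket(x, "sym2", mode="periodization", maxlevel=levels)
        ref = np.array([np.sum(node.data ** 2)
                        for node in wp.get_level(levels, order="freq")])
        np.testing.assert_allclose(spec.energies, ref, rtol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(300, 3000), st.integers(1, 9))
    def test_parseval_energy_conservation(self, seed, length, levels):
        x = np.random.default_rng(seed).normal(size=length)
        spec = wp_decompose(_signal(x), levels=levels)
        total = np.sum(x ** 2)
        assert abs(spec.total_energy - total) / total < 1e-8

    def test_refinement_consistency(self, rng):
        x = rng.normal(size=2048)
        for levels in (2, 5, 9):
            fine = wp_decompose(_signal(x), levels=levels).energies
            coarse = wp_decompose(_signal(x), levels=levels - 1).energies
            np.testing.assert_allclose(fine.reshape(-1, 2).sum(axis=1), coarse,
                                       rtol=1e-8)

    def test_tone_lands_in_fourier_predicted_band(self, rng):
        fs, levels, n = 5000.0, 9, 4096
        t = np.arange(n) / fs
        for f0 in (250.0, 997.0, 1843.5, 2301.0):
            x = np.sin(2 * np.pi * f0 * t)
            spec = wp_decompose(_signal(x), levels=levels)
            freqs = np.fft.rfftfreq(n, 1 / fs)
            f_peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
            predicted = int(f_peak / spec.band_width)
            assert abs(int(np.argmax(spec.energies)) - predicted) <= 1

    def test_tone_argmax_band_monotone_in_frequency(self):
        fs, n = 5000.0, 4096
        t = np.arange(n) / fs
        bands = [int(np.argmax(wp_decompose(_signal(np.sin(2 * np.pi * f * t)),
                                            levels=9).energies))
                 for f in (50, 300, 700, 1200, 1900, 2400)]
        assert bands == sorted(bands)

    def test_level_bounds_rejected(self, rng):
        sig = _signal(rng.normal(size=64))
        with pytest.raises(ValueError):
            wp_decompose(sig, levels=-1)
        with pytest.raises(ValueError, match="cap"):
            wp_decompose(sig, levels=17)


class TestFrequencyOrder:
    @pytest.mark.parametrize("level", [0, 1])
    def test_identity_at_shallow_levels(self, level):
        for i in range(2 ** level):
            assert frequency_order(i, level) == i

    def test_level_two_gray_code(self):
        assert [frequency_order(i, 2) for i in range(4)] == [0, 1, 3, 2]

    def test_level_two_tone_oracle(self):
        # Decompose pure tones at the four level-2 band centers and check
        # which natural node captures each: the observed permutation is the
        # Gray-code map.
        fs, n = 5000.0, 4096
        t = np.arange(n) / fs
        df = fs / 8  # level-2 band width
        observed = {}
        for band in range(4):
            x = np.sin(2 * np.pi * (band + 0.5) * df * t)
            nodes = wp_coefficients(x, 2)
            natural = int(np.argmax([np.sum(c ** 2) for c in nodes]))
            observed[natural] = band
        assert observed == {i: frequency_order(i, 2) for i in range(4)}

    @pytest.mark.parametrize("level", [3, 5, 8])
    def test_bijective(self, level):
        image = {frequency_order(i, level) for i in range(2 ** level)}
        assert image == set(range(2 ** level))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            frequency_order(4, 2)


class TestBandRange:
    def test_first_band_of_paper_configuration(self):
        low, high = band_range(0, 9, 5000.0)
        assert low == 0.0
        assert round(high, 2) == 4.88

    def test_last_band_reaches_nyquist(self):
        _, high = band_range(511, 9, 5000.0)
        assert high == pytest.approx(2500.0, rel=1e-12)

    @pytest.mark.parametrize("level", [1, 4, 9])
    def test_bands_tile_zero_to_nyquist(self, level):
        fs = 5000.0
        edges = [band_range(j, level, fs) for j in range(2 ** level)]
        assert edges[0][0] == 0.0
        assert edges[-1][1] == pytest.approx(fs / 2)
        for (_, hi), (lo, _) in zip(edges[:-1], edges[1:]):
            assert hi == pytest.approx(lo)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            band_range(512, 9, 5000.0)
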