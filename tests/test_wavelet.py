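import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swdscore import (BandEnergySeries, Recording, WaveletConfig, band_energy,
                      band_energy_series, morlet_cwt, moving_average,
                      smooth_energy)
from conftest import tone


def fft_band_power(x: np.ndarray, fs: float, band: tuple[float, float]
                   ) -> float:
    """Independent band-power oracle: integrated periodogram."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(spec[(f >= band[0]) & (f <= band[1])].sum())


class TestWaveletConfig:
    def test_defaults_cover_four_bands(self):
        cfg = WaveletConfig()
        assert set(cfg.bands) == {"swd_low", "swd_mid", "swd_high", "sleep"}
        assert cfg.omega0 == pytest.approx(2 * np.pi)

    def test_freq_step_wider_than_narrowest_band_rejected(self):
        with pytest.raises(ValueError):
            WaveletConfig(freq_step=2.5)

    def test_band_grid_includes_edges(self):
        grid = WaveletConfig().band_freqs("swd_low")
        assert grid[0] == pytest.approx(2.5)
        assert grid[-1] == pytest.approx(4.5)


class TestMorletCwt:
    def test_tone_energy_localises_in_frequency(self):
        # CWT energy at the tone frequency must dominate a distant
        # frequency by far more than the 10x the FFT oracle predicts
        rec = tone(16.5, duration_s=30.0)
        coeffs = morlet_cwt(rec, 0, [3.5, 16.5])
        interior = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        e_off = np.mean(np.abs(coeffs[0, interior]) ** 2)
        e_on = np.mean(np.abs(coeffs[1, interior]) ** 2)
        x = rec.signals[0]
        oracle = fft_band_power(x, rec.fs, (16.0, 17.0)) / max(
            fft_band_power(x, rec.fs, (3.0, 4.0)), 1e-30)
        assert oracle >= 10.0
        assert e_on / e_off >= 10.0

    def test_zero_signal_gives_zero_coefficients(self):
        rec = Recording(np.zeros((1, 4000)), fs=400.0)
        coeffs = morlet_cwt(rec, 0, [5.0, 10.0])
        assert np.all(coeffs == 0)

    def test_linearity_in_amplitude(self):
        rec1 = tone(9.0, duration_s=5.0)
        rec2 = tone(9.0, duration_s=5.0, amplitude=2.0)
        c1 = morlet_cwt(rec1, 0, [9.0])
        c2 = morlet_cwt(rec2, 0, [9.0])
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-9)

    def test_frequency_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_cwt(tone(5.0), 0, [250.0])

    def test_peak_response_at_tone_frequency(self):
        # scale-to-frequency mapping: response across a frequency grid
        # peaks at the tone frequency (omega0 = 2*pi convention)
        rec = tone(11.0, duration_s=20.0)
        freqs = np.arange(5.0, 18.1, 0.5)
        coeffs = morlet_cwt(rec, 0, freqs)
        interior = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        profile = np.mean(np.abs(coeffs[:, interior]) ** 2, axis=1)
        assert freqs[np.argmax(profile)] == pytest.approx(11.0)

    def test_agrees_with_pywavelets_profile(self):
        # independent implementation cross-check: normalised frequency
        # response to a tone matches pywt's complex Morlet CWT
        pywt = pytest.importorskip("pywt")
        rec = tone(9.5, duration_s=20.0)
        freqs = np.arange(6.0, 14.1, 0.5)
        ours = morlet_cwt(rec, 0, freqs)
        # cmor2.0-1.0 is the complex Morlet with envelope exp(-t^2/2) and
        # centre frequency 1/scale -- the same wavelet up to normalisation
        scales = pywt.frequency2scale("cmor2.0-1.0", freqs / rec.fs)
        theirs, _ = pywt.cwt(rec.signals[0], scales, "cmor2.0-1.0",
                             sampling_period=1.0 / rec.fs)
        interior = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        p_ours = np.mean(np.abs(ours[:, interior]) ** 2, axis=1)
        p_theirs = np.mean(np.abs(theirs[:, interior]) ** 2, axis=1)
        corr = np.corrcoef(p_ours / p_ours.max(), p_theirs / p_theirs.max())
        assert corr[0, 1] > 0.98


class TestBandEnergy:
    def test_zero_coefficients_give_zero_series(self):
        coeffs = np.zeros((3, 100), dtype=complex)
        series = band_energy(coeffs, [2.5, 3.0, 3.5], (2.5, 3.5))
        assert np.all(series.values == 0)

    def test_single_frequency_grid_degenerates_to_magnitude_square(self):
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=(1, 50)) + 1j * rng.normal(size=(1, 50))
        series = band_energy(coeffs, [9.0], (8.0, 10.0))
        np.testing.assert_allclose(series.values, np.abs(coeffs[0]) ** 2)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            band_energy(np.zeros((2, 10), dtype=complex), [5.0, 6.0],
                        (15.0, 18.0))

    @pytest.mark.parametrize("freq,in_band,out_band", [
        (16.5, "swd_high", "swd_low"),
        (3.5, "swd_low", "swd_high"),
        (7.5, "sleep", "swd_mid"),
    ])
    def test_in_band_tone_dominates_disjoint_band(self, freq, in_band,
                                                  out_band):
        rec = tone(freq, duration_s=30.0)
        e_in = band_energy_series(rec, 0, in_band).values
        e_out = band_energy_series(rec, 0, out_band).values
        interior = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        assert e_in[interior].mean() >= 10.0 * e_out[interior].mean()
        # FFT oracle agrees on the direction
        x = rec.signals[0]
        cfg = WaveletConfig()
        assert fft_band_power(x, rec.fs, cfg.bands[in_band]) > \
            10.0 * fft_band_power(x, rec.fs, cfg.bands[out_band])

    def test_energy_nonnegative_and_quadratic_scaling(self):
        rec, _ = _noise_recording()
        e1 = band_energy_series(rec, 0, "sleep").values
        e2 = band_energy_series(rec.scaled(3.0), 0, "sleep").values
        assert np.all(e1 >= 0)
        np.testing.assert_allclose(e2, 9.0 * e1, rtol=1e-7)


def _noise_recording(seed: int = 5):
    rng = np.random.default_rng(seed)
    return Recording(rng.normal(size=(1, 8000)), fs=400.0), rng


class TestSmoothEnergy:
    def _series(self, values, fs=400.0):
        return BandEnergySeries(np.asarray(values, float), fs=fs)

    def test_constant_series_unchanged(self):
        out = smooth_energy(self._series(np.full(1000, 3.25)), 0.25)
        np.testing.assert_allclose(out.values, 3.25)

    def test_unit_impulse_becomes_plateau(self):
        x = np.zeros(1001)
        x[500] = 1.0
        k = 100  # 0.25 s at 400 Hz
        out = smooth_energy(self._series(x), 0.25)
        plateau = out.values[out.values > 0]
        assert len(plateau) == k
        np.testing.assert_allclose(plateau, 1.0 / k)

    def test_matches_direct_summation_oracle(self):
        # brute-force per-sample truncated-window means, independent of
        # the cumulative-sum implementation
        rng = np.random.default_rng(2)
        x = rng.random(500)
        k = 9
        oracle = np.array([x[max(0, i - (k - 1) // 2):
                             min(len(x), i + k // 2 + 1)].mean()
                           for i in range(len(x))])
        np.testing.assert_allclose(moving_average(x, k), oracle, rtol=1e-12)

    def test_mean_nearly_preserved_for_long_series(self):
        # edge truncation perturbs the global mean only through the
        # outermost window of samples: O(window/length) relative effect
        rng = np.random.default_rng(2)
        x = rng.random(200_000)
        out = smooth_energy(self._series(x), 0.5)
        assert out.values.mean() == pytest.approx(x.mean(), rel=1e-4)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_energy(self._series(np.ones(100)), 0.001)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=2, max_value=40))
    @settings(max_examples=25, deadline=None)
    def test_order_preservation_and_positive_scaling(self, seed, k):
        # smoothing commutes with positive scaling and preserves ordering
        # under constant shifts
        rng = np.random.default_rng(seed)
        x = rng.random(200)
        a = moving_average(x, k)
        np.testing.assert_allclose(moving_average(2.5 * x, k), 2.5 * a,
                                   rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(moving_average(x + 1.0, k), a + 1.0,
                                   rtol=1e-9, atol=1e-9)
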