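import numpy as np
import pytest

from dielpredict import (cross_wavelet, cwt_morlet, detrend_linear, fft_amplitude_24h,
                         red_noise_significance)
from dielpredict.spectral import FOURIER_FACTOR, ar1_spectrum, estimate_ar1

from conftest import ar1_series, diel_cosine, make_series


class TestCwtMorlet:
    def test_single_tone_peak_at_24h(self, tone_30d):
        res = cwt_morlet(detrend_linear(tone_30d))
        peak = res.period[np.argmax(res.power.mean(axis=1))]
        # within one geometric scale step (dj = 1/12) of 24 h
        assert abs(np.log2(peak / 24.0)) <= 1.0 / 12

    def test_matches_pywavelets_peak(self, tone_30d):
        # independent implementation agrees on where the tone lives
        import pywt
        x = detrend_linear(tone_30d).x
        scales = np.geomspace(4, 512, 60)
        coeffs, freqs = pywt.cwt(x, scales, "cmor1.5-1.0", sampling_period=600.0)
        peak_h = 1.0 / freqs[np.argmax(np.abs(coeffs).mean(axis=1))] / 3600.0
        ours = cwt_morlet(detrend_linear(tone_30d))
        our_peak = ours.period[np.argmax(ours.power.mean(axis=1))]
        assert abs(np.log2(peak_h / our_peak)) < 0.15

    def test_constant_series_zero_power(self):
        res = cwt_morlet(make_series(np.full(512, 3.0)))
        assert res.power.max() < 1e-12

    def test_white_noise_unit_mean_power(self):
        means = [cwt_morlet(ar1_series(4096, 0.0, seed=s)).power.mean() for s in range(5)]
        assert np.mean(means) == pytest.approx(1.0, rel=0.15)

    def test_variance_reconstruction_broadband(self):
        # scale-integrated power rebuilds the variance within 20% (Cdelta = 0.776)
        s = ar1_series(2048, 0.5, seed=3)
        res = cwt_morlet(s)
        recon = (1.0 / 12) * res.dt / (0.776 * s.n) * (res.power / res.scales[:, None]).sum()
        assert recon == pytest.approx(1.0, rel=0.2)

    def test_coi_symmetry(self):
        res = cwt_morlet(ar1_series(500, 0.0, seed=1))
        np.testing.assert_allclose(res.coi_period, res.coi_period[::-1])

    def test_coi_rises_to_mid_series(self):
        res = cwt_morlet(ar1_series(500, 0.0, seed=1))
        mid = res.coi_period[250]
        assert res.coi_period[0] == 0.0 and mid == res.coi_period.max()

    def test_short_or_irregular_series_rejected(self):
        with pytest.raises(ValueError):
            cwt_morlet(make_series([1.0, 2.0, 3.0]))
        s = ar1_series(100, 0.0)
        irr = s.replace(t=s.t.delete(50), x=np.delete(s.x, 50))
        with pytest.raises(ValueError, match="regularized"):
            cwt_morlet(irr)

    def test_fourier_factor_convention(self):
        assert FOURIER_FACTOR == pytest.approx(1.033, abs=1e-3)


class TestRedNoiseSignificance:
    def test_strong_tone_significant(self):
        s = ar1_series(4096, 0.5, sd=1.0, seed=7)
        ts = np.arange(s.n) * 600.0
        s = s.replace(x=s.x + 3.0 * np.cos(2 * np.pi * ts / 86400.0))
        res = red_noise_significance(cwt_morlet(s), s)
        i24 = np.argmin(np.abs(np.log(res.period / 24.0)))
        ok = res.coi_period >= 24.0
        assert (res.sig_ratio[i24][ok] > 1).mean() > 0.9

    def test_white_override_flat_threshold(self):
        s = ar1_series(1024, 0.6, seed=2)
        res = red_noise_significance(cwt_morlet(s), s, ar1_override=0.0)
        # threshold = power / sig_ratio must be scale-independent for white noise
        thr = res.power / res.sig_ratio
        thr_per_scale = np.nanmedian(np.where(res.power > 0, thr, np.nan), axis=1)
        np.testing.assert_allclose(thr_per_scale, thr_per_scale[0], rtol=1e-9)

    def test_nonstationary_ar1_rejected(self):
        s = ar1_series(512, 0.5, seed=9)
        res = cwt_morlet(s)
        with pytest.raises(ValueError, match="detrend"):
            red_noise_significance(res, s, ar1_override=1.0)

    def test_ar1_spectrum_white_limit(self):
        assert np.allclose(ar1_spectrum(0.0, 600.0, np.array([3600.0, 86400.0])), 1.0)

    def test_estimate_ar1_recovers_phi(self):
        s = ar1_series(20000, 0.7, seed=11)
        assert estimate_ar1(s.x) == pytest.approx(0.7, abs=0.03)


class TestCrossWavelet:
    def test_self_coherence_zero_phase(self, tone_30d):
        a = detrend_linear(tone_30d)
        res = cross_wavelet(a, a.replace(variable="oxygen_saturation"))
        sig = res.sig_ratio > 1
        assert np.abs(res.phase[sig]).max() < 1e-8

    def test_antiphase_pi(self, tone_30d):
        a = detrend_linear(tone_30d)
        b = a.replace(variable="oxygen_saturation", x=-a.x)
        res = cross_wavelet(a, b)
        sig = res.sig_ratio > 1
        assert np.abs(np.abs(res.phase[sig]) - np.pi).max() < 1e-8

    def test_one_hour_lag_phase(self):
        a = detrend_linear(diel_cosine(30, mean=0.0))
        b = detrend_linear(diel_cosine(30, mean=0.0, phase=3600.0,
                                       variable="oxygen_saturation"))
        res = cross_wavelet(a, b)
        i24 = np.argmin(np.abs(np.log(res.period / 24.0)))
        ok = res.coi_period >= 24.0
        assert np.abs(np.mean(res.phase[i24][ok]) - 2 * np.pi / 24) < 0.03

    def test_phase_antisymmetry(self):
        a = detrend_linear(ar1_series(1024, 0.3, seed=5))
        b = detrend_linear(ar1_series(1024, 0.3, seed=6,
                                      variable="oxygen_saturation"))
        ab = cross_wavelet(a, b)
        ba = cross_wavelet(b, a)
        diff = np.angle(np.exp(1j * (ab.phase + ba.phase)))
        assert np.abs(diff).max() < 1e-8

    def test_mismatched_grids_rejected(self):
        a = ar1_series(100, 0.0, seed=1)
        b = ar1_series(100, 0.0, seed=2, start="2021-02-01",
                       variable="oxygen_saturation")
        with pytest.raises(ValueError, match="grid"):
            cross_wavelet(a, b)


class TestFftAmplitude:
    def test_pure_tone_exact(self):
        amp = fft_amplitude_24h(diel_cosine(32, amplitude=5.0))
        assert amp.amplitude == pytest.approx(5.0, abs=0.05)

    def test_constant_zero(self):
        assert fft_amplitude_24h(make_series(np.full(2 * 144, 9.0))).amplitude == 0.0

    def test_two_tone_separation(self):
        s = diel_cosine(32, amplitude=5.0, mean=0.0)
        ts = np.arange(s.n) * 600.0
        s = s.replace(x=s.x + 2.0 * np.cos(2 * np.pi * ts / (12 * 3600.0)))
        assert fft_amplitude_24h(s).amplitude == pytest.approx(5.0, abs=0.05)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="2"):
            fft_amplitude_24h(diel_cosine(1.5))


def test_wavelet_result_serializes_to_dataset(tone_30d):
    s = detrend_linear(tone_30d)
    res = red_noise_significance(cwt_morlet(s), s)
    ds = res.to_dataset()
    assert set(ds.data_vars) == {"power", "coi_period", "sig_ratio"}
    assert ds["power"].dims == ("period", "time")
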