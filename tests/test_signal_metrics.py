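import math

import numpy as np
import pytest
from scipy import stats

from phonoid.signal_metrics import (
    Signal,
    bispectrum,
    cross_correlation,
    error_metrics,
    frequency_response,
    impulse_response,
    metrics_report,
    paired_ttest,
    power_at_frequencies,
    snr_db,
    spectrogram,
    welch_psd,
)
from conftest import make_noise, make_tone


class TestSnr:
    def test_identical_signals_give_inf(self):
        x = make_tone(50.0)
        assert snr_db(x, x) == math.inf

    def test_known_power_ratio(self):
        # orthogonal sinusoids over integer cycles: P_sig = 1, P_noise = 1/4
        fs, dur = 1000.0, 2.0
        t = np.arange(round(fs * dur)) / fs
        x = Signal(math.sqrt(2) * np.sin(2 * np.pi * 50 * t), fs)
        y = Signal(x.samples + math.sqrt(2) / 2 * np.sin(2 * np.pi * 150 * t), fs)
        assert snr_db(x, y) == pytest.approx(10 * math.log10(4), abs=1e-9)
        assert snr_db(x, y) == pytest.approx(6.0206, abs=1e-3)

    def test_zero_output_gives_zero_db(self):
        x = make_tone(50.0)
        y = Signal(np.zeros(len(x)), x.sample_rate)
        assert snr_db(x, y) == pytest.approx(0.0, abs=1e-12)


class TestWelchPsd:
    def test_peak_at_tone_frequency(self):
        spec = welch_psd(make_tone(50.0, fs=1000.0, duration=4.0))
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(50.0, abs=1.0)

    def test_parseval_white_noise(self):
        x = make_noise(n=2**13, sd=1.7, seed=4)
        spec = welch_psd(x)
        assert spec.total_power() == pytest.approx(x.samples.var(), rel=0.10)

    def test_constant_signal_detrended(self):
        x = Signal(np.full(2048, 3.0), 100.0)
        spec = welch_psd(x)
        assert np.max(spec.power) < 1e-20

    def test_segment_too_long(self):
        with pytest.raises(ValueError):
            welch_psd(make_noise(n=100), segment_length=256)


class TestCrossCorrelation:
    def test_self_correlation_peak(self):
        x = make_noise(n=2000, seed=1)
        xc = cross_correlation(x, x)
        assert xc.max_value == pytest.approx(1.0, abs=1e-12)
        assert xc.lag_at_max == 0.0

    def test_delay_detected_with_positive_lag(self):
        fs, k = 500.0, 25
        base = np.random.default_rng(2).normal(size=3000)
        x = Signal(base, fs)
        delayed = Signal(np.concatenate([np.zeros(k), base[:-k]]), fs)
        xc = cross_correlation(x, delayed)
        assert xc.lag_at_max == pytest.approx(k / fs)

    def test_anticorrelation(self):
        x = make_noise(n=1000, seed=3)
        y = Signal(-x.samples, x.sample_rate)
        xc = cross_correlation(x, y)
        assert xc.max_value == pytest.approx(-1.0, abs=1e-12)
        assert xc.lag_at_max == 0.0

    def test_bounded_in_unit_interval(self, rng):
        x = Signal(rng.normal(size=500), 100.0)
        y = Signal(rng.normal(size=500), 100.0)
        xc = cross_correlation(x, y)
        assert np.all(np.abs(xc.values) <= 1.0 + 1e-12)

    def test_zero_signal_rejected(self):
        x = make_noise(n=100)
        z = Signal(np.zeros(100), x.sample_rate)
        with pytest.raises(ValueError):
            cross_correlation(x, z)


class TestErrorMetrics:
    def test_identity(self):
        x = make_tone(20.0)
        rmse, mae, psnr, r = error_metrics(x, x)
        assert rmse == 0.0 and mae == 0.0
        assert psnr == math.inf
        assert r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x = Signal([0.0, 1.0], 1.0)
        y = Signal([0.0, 0.0], 1.0)
        with pytest.raises(ValueError):
            error_metrics(x, y)  # zero-variance output: Pearson undefined
        rmse = math.sqrt(np.mean((y.samples - x.samples) ** 2))
        assert rmse == pytest.approx(1 / math.sqrt(2))

    def test_rmse_mae_psnr_values(self):
        x = Signal([0.0, 1.0, 0.5], 1.0)
        y = Signal([0.0, 0.0, 1.0], 1.0)
        rmse, mae, psnr, r = error_metrics(x, y)
        assert rmse == pytest.approx(math.sqrt((1.0 + 0.25) / 3))
        assert mae == pytest.approx(0.5)
        assert psnr == pytest.approx(20 * math.log10(1.0 / rmse))

    def test_perfect_anticorrelation(self):
        x = Signal([-1.0, 0.0, 1.0], 1.0)
        y = Signal([1.0, 0.0, -1.0], 1.0)
        *_, r = error_metrics(x, y)
        assert r == pytest.approx(-1.0)


class TestPowerAtFrequencies:
    def test_tone_dominates_its_bin(self):
        x = make_tone(144.0, fs=2000.0, duration=4.0)
        p144, p233 = power_at_frequencies(x, [144.0, 233.0])
        assert p144 / p233 > 100

    def test_silence(self):
        x = Signal(np.zeros(4096), 2000.0)
        powers = power_at_frequencies(x, [144.0, 233.0])
        assert np.all(powers < 1e-20)

    def test_equal_tones_equal_power(self):
        fs, dur = 2000.0, 8.0
        t = np.arange(round(fs * dur)) / fs
        x = Signal(np.sin(2 * np.pi * 144 * t) + np.sin(2 * np.pi * 610 * t), fs)
        p1, p2 = power_at_frequencies(x, [144.0, 610.0])
        assert p1 == pytest.approx(p2, rel=0.05)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            power_at_frequencies(make_tone(50.0), [500.0])


class TestFrequencyResponse:
    def test_scalar_gain(self):
        x = make_noise(n=2**14, seed=5)
        y = Signal(0.5 * x.samples, x.sample_rate)
        fr = frequency_response(x, y)
        assert np.median(fr.magnitude) == pytest.approx(0.5, rel=1e-6)
        assert np.max(np.abs(fr.phase[1:-1])) < 1e-6

    def test_delay_gives_linear_phase(self):
        fs, d = 1000.0, 5
        base = np.random.default_rng(6).normal(size=2**14)
        x = Signal(base, fs)
        y = Signal(np.roll(base, d), fs)
        fr = frequency_response(x, y, segment_length=1024)
        # fit phase slope over the lower half of the band
        sel = (fr.frequencies > 5) & (fr.frequencies < 200)
        slope = stats.linregress(fr.frequencies[sel], np.unwrap(fr.phase)[sel]).slope
        assert slope == pytest.approx(-2 * np.pi * d / fs, rel=0.02)

    def test_fir_round_trip_exact(self):
        # circular convolution + single rectangular segment makes the Welch
        # ratio exact, so irfft recovers the kernel to machine precision
        rng = np.random.default_rng(7)
        n = 2048
        kernel = np.zeros(n)
        kernel[:8] = [0.5, 0.3, -0.2, 0.1, 0.05, -0.02, 0.01, 0.004]
        x = rng.normal(size=n)
        y = np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(kernel)))
        fr = frequency_response(
            Signal(x, 1000.0), Signal(y, 1000.0),
            segment_length=n, overlap=0, window="boxcar", detrend=False,
            regularization=0.0,
        )
        h = impulse_response(fr)
        assert np.max(np.abs(h - kernel)) < 1e-6


class TestImpulseResponse:
    def test_identity_transfer_is_unit_impulse(self):
        H = np.ones(129, dtype=complex)
        h = impulse_response(H)
        assert h[0] == pytest.approx(1.0)
        assert np.max(np.abs(h[1:])) < 1e-12

    def test_pure_delay_shifts_impulse(self):
        nf, d = 129, 7
        f = np.arange(nf) / (2 * (nf - 1))  # normalized frequency
        H = np.exp(-2j * np.pi * f * d)
        h = impulse_response(H)
        assert np.argmax(np.abs(h)) == d
        assert h[d] == pytest.approx(1.0, abs=1e-9)

    def test_first_order_lowpass_kernel_decay(self):
        fs, n = 1000.0, 4096
        tau = 0.02
        freqs = np.fft.rfftfreq(n, d=1 / fs)
        H = 1.0 / (1.0 + 2j * np.pi * freqs * tau)
        h = impulse_response(H)
        k = np.arange(1, 60)
        slope = stats.linregress(k / fs, np.log(h[k])).slope
        assert -1.0 / slope == pytest.approx(tau, rel=0.05)


class TestBispectrum:
    @staticmethod
    def _three_tones(fs, n_seg, n_segments, f1, f2, coupled, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(n_seg) / fs
        segs = []
        for _ in range(n_segments):
            p1, p2 = rng.uniform(0, 2 * np.pi, 2)
            p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
            seg = (
                np.cos(2 * np.pi * f1 * t + p1)
                + np.cos(2 * np.pi * f2 * t + p2)
                + np.cos(2 * np.pi * (f1 + f2) * t + p3)
            )
            segs.append(seg)
        return Signal(np.concatenate(segs), fs)

    def test_quadratic_phase_coupling_peak_location(self):
        fs, n_seg = 1000.0, 256
        x = self._three_tones(fs, n_seg, 64, 125.0, 187.5, coupled=True, seed=8)
        b = bispectrum(x, n_seg, window=None)
        f1, f2, _ = b.peak()
        assert sorted([f1, f2]) == pytest.approx([125.0, 187.5])

    def test_uncoupled_phases_suppress_peak(self):
        fs, n_seg = 1000.0, 256
        coupled = self._three_tones(fs, n_seg, 64, 125.0, 187.5, coupled=True, seed=9)
        uncoupled = self._three_tones(fs, n_seg, 64, 125.0, 187.5, coupled=False, seed=9)
        bc = bispectrum(coupled, n_seg, window=None)
        bu = bispectrum(uncoupled, n_seg, window=None)
        i = np.argmin(np.abs(bc.frequencies - 125.0))
        j = np.argmin(np.abs(bc.frequencies - 187.5))
        assert bc.magnitude[i, j] / bu.magnitude[i, j] > 10

    def test_gaussian_noise_flat(self):
        fs, n_seg = 1000.0, 256
        coupled = self._three_tones(fs, n_seg, 64, 125.0, 187.5, coupled=True, seed=10)
        noise = Signal(np.random.default_rng(10).normal(size=64 * n_seg), fs)
        bc = bispectrum(coupled, n_seg, window=None)
        bn = bispectrum(noise, n_seg, window=None)
        assert bc.magnitude.max() / bn.magnitude.max() > 10

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            bispectrum(make_noise(n=500), 256)


class TestSpectrogram:
    def test_stationary_tone_constant_ridge(self):
        x = make_tone(100.0, fs=1000.0, duration=4.0)
        f, t, S = spectrogram(x, window_length=256, hop=128)
        ridge = f[np.argmax(S, axis=0)]
        interior = ridge[2:-2]
        assert np.allclose(interior, 100.0, atol=4.0)

    def test_chirp_ridge_monotone(self):
        from scipy.signal import chirp

        fs = 2000.0
        t = np.arange(8000) / fs
        x = Signal(chirp(t, f0=50, f1=600, t1=t[-1]), fs)
        f, tt, S = spectrogram(x, window_length=256, hop=64)
        ridge = f[np.argmax(S, axis=0)][3:-3]
        assert np.all(np.diff(ridge) >= 0)
        assert ridge[-1] > ridge[0] + 400

    def test_am_tone_ridge_oscillates_at_fmod(self):
        fs, f_carrier, f_mod = 4000.0, 400.0, 10.0
        t = np.arange(int(4 * fs)) / fs
        x = Signal((1 + 0.9 * np.sin(2 * np.pi * f_mod * t)) * np.sin(2 * np.pi * f_carrier * t), fs)
        f, tt, S = spectrogram(x, window_length=128, hop=16)
        ridge_mag = S[np.argmin(np.abs(f - f_carrier)), :]
        ridge_mag = ridge_mag - ridge_mag.mean()
        dt_frames = 16 / fs
        spec = np.abs(np.fft.rfft(ridge_mag))
        freqs = np.fft.rfftfreq(ridge_mag.size, d=dt_frames)
        assert freqs[np.argmax(spec)] == pytest.approx(f_mod, abs=0.5)

    def test_bad_hop(self):
        with pytest.raises(ValueError):
            spectrogram(make_tone(10.0), window_length=64, hop=0)


class TestPairedTtest:
    def test_identical_signals(self):
        x = make_noise(n=100, seed=11)
        assert paired_ttest(x, x) == 1.0

    def test_constant_shift_detected(self):
        x = make_noise(n=1000, seed=12)
        y = Signal(x.samples + 10.0, x.sample_rate)
        assert paired_ttest(x, y) < 1e-6

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(200):
            a = Signal(rng.normal(size=100), 1.0)
            b = Signal(rng.normal(size=100), 1.0)
            ps.append(paired_ttest(a, b))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestInvariances:
    def test_metrics_ignore_time_offset(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=4096)
        out = 0.3 * base + 0.05 * rng.normal(size=4096)
        r1 = metrics_report(Signal(base, 500.0, t0=0.0), Signal(out, 500.0, t0=0.0))
        r2 = metrics_report(Signal(base, 500.0, t0=123.4), Signal(out, 500.0, t0=123.4))
        assert r1.snr_db == r2.snr_db
        assert r1.rmse == r2.rmse
        assert r1.pearson_r == r2.pearson_r
        assert r1.max_xcorr == r2.max_xcorr

    def test_report_fields_consistent(self):
        rng = np.random.default_rng(15)
        x = Signal(rng.normal(size=8192), 2000.0)
        y = Signal(0.01 * x.samples + 0.001 * rng.normal(size=8192), 2000.0)
        rep = metrics_report(x, y)
        assert abs(rep.pearson_r) <= 1.0
        assert abs(rep.max_xcorr) <= 1.0
        assert rep.rmse >= 0 and rep.mae >= 0
        assert set(rep.power_at_freqs) == {144.0, 233.0, 377.0, 610.0, 987.0}
        d = rep.to_dict()
        assert d["sample_rate_hz"] == 2000.0
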