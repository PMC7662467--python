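"""Amplitude-ratio, frequency-ratio and SpO2 features."""
import numpy as np
import pytest

from apneakit.core_io import SignalStream
from apneakit.features import (FEATURE_NAMES, WindowScheme, amplitude_ratio,
                               amplitude_ratio_series, assemble_frames,
                               frequency_ratio, spo2_features)

SCHEME = WindowScheme()


def amp_stream(values, fs=50.0):
    return SignalStream(np.asarray(values, float), fs)


def piecewise(fs, *spans):
    """Concatenate (duration_s, value) spans into one stream."""
    parts = [np.full(int(d * fs), v) for d, v in spans]
    return amp_stream(np.concatenate(parts), fs)


class TestAmplitudeRatio:
    def test_constant_envelope_gives_one(self):
        s = piecewise(50.0, (80, 3.0))
        assert amplitude_ratio(s, SCHEME, 0) == pytest.approx(1.0, abs=1e-9)

    def test_halved_envelope_gives_half(self):
        s = piecewise(50.0, (60, 2.0), (20, 1.0))
        assert amplitude_ratio(s, SCHEME, 0) == pytest.approx(0.5, abs=1e-9)

    def test_apnea_limit_gives_zero(self):
        s = piecewise(50.0, (60, 1.0), (20, 0.0))
        assert amplitude_ratio(s, SCHEME, 0) == pytest.approx(0.0, abs=1e-9)

    def test_frame_before_first_pw_rejected(self):
        s = piecewise(50.0, (30, 1.0))
        with pytest.raises(ValueError, match="full PW"):
            amplitude_ratio(s, SCHEME, 0)

    @pytest.mark.parametrize("k", [0.01, 1.0, 250.0])
    def test_scale_invariance(self, rng, k):
        base = 1.0 + 0.3 * rng.random(int(90 * 50))
        a1 = amplitude_ratio(amp_stream(base), SCHEME, 10)
        a2 = amplitude_ratio(amp_stream(k * base), SCHEME, 10)
        assert a2 == pytest.approx(a1, rel=1e-6)

    def test_series_matches_scalar_path(self, rng):
        s = amp_stream(1.0 + rng.random(int(120 * 50)))
        times = SCHEME.frame_times(120.0)
        series = amplitude_ratio_series(s, SCHEME, times)
        scalars = [amplitude_ratio(s, SCHEME, n) for n in range(times.size)]
        np.testing.assert_allclose(series, scalars, rtol=1e-12)


def periodogram_fr_oracle(seg, fs):
    """Independent brute-force band-energy ratio on the FFT grid."""
    n = seg.size
    freqs = np.arange(n // 2 + 1) * fs / n
    power = np.abs(np.fft.rfft(seg)) ** 2
    num = np.trapezoid(power[(freqs >= 0.8) & (freqs <= 1.5)],
                       freqs[(freqs >= 0.8) & (freqs <= 1.5)])
    den = np.trapezoid(power[(freqs >= 0.1) & (freqs <= 0.8)],
                       freqs[(freqs >= 0.1) & (freqs <= 0.8)])
    return np.log10(num / den)


class TestFrequencyRatio:
    def fr_of(self, x, fs=50.0):
        pad = np.zeros(int(60 * fs))                 # PW region, unused by FR
        return frequency_ratio(SignalStream(np.concatenate([pad, x]), fs),
                               SCHEME, 0)

    def test_respiratory_tone_is_negative(self):
        t = np.arange(0, 10, 1 / 50)
        x = np.sin(2 * np.pi * 0.3 * t)
        fr = self.fr_of(x)
        assert fr < -1
        assert fr == pytest.approx(
            np.clip(periodogram_fr_oracle(x, 50.0), -6, 6), abs=1e-9)

    def test_cardiac_tone_is_positive(self):
        t = np.arange(0, 10, 1 / 50)
        x = np.sin(2 * np.pi * 1.0 * t)
        fr = self.fr_of(x)
        assert fr > 1
        assert fr == pytest.approx(
            np.clip(periodogram_fr_oracle(x, 50.0), -6, 6), abs=1e-9)

    def test_unequal_mixture_matches_oracle_unclipped(self):
        t = np.arange(0, 10, 1 / 50)
        x = np.sin(2 * np.pi * 0.3 * t) + 0.3 * np.sin(2 * np.pi * 1.1 * t)
        fr = self.fr_of(x)
        oracle = periodogram_fr_oracle(x, 50.0)
        assert -6 < oracle < 0
        assert fr == pytest.approx(oracle, abs=1e-9)

    def test_equal_power_mixture_near_zero(self):
        t = np.arange(0, 10, 1 / 50)
        x = np.sin(2 * np.pi * 0.3 * t) + np.sin(2 * np.pi * 1.0 * t)
        assert abs(self.fr_of(x)) <= 0.15

    def test_all_zero_segment_floors(self):
        assert self.fr_of(np.zeros(500)) == -6.0

    def test_amplitude_invariance(self):
        t = np.arange(0, 10, 1 / 50)
        x = np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 1.2 * t)
        assert self.fr_of(x) == pytest.approx(self.fr_of(17.0 * x), abs=1e-9)


class TestSpo2Features:
    def test_constant_trace_all_zero(self, caplog):
        s = SignalStream(np.full(200, 97.0), 1.0)
        _, f = spo2_features(s, SCHEME, np.array([60.0]))
        np.testing.assert_allclose(f, 0.0)

    def test_linear_decline_derivative_mean(self):
        """1 % decline over the 20-s delayed segment: d_mean = -0.05/s on the
        raw scale, divided by the whole-night SD by normalization."""
        x = np.full(300, 97.0)
        x[140:160] = 97.0 - np.arange(20) * 0.05     # inside [t+20, t+40)
        x[160:] = x[159]
        s = SignalStream(x, 1.0)
        sd = np.std(x)
        _, f = spo2_features(s, SCHEME, np.array([120.0]))
        base, d_min, d_max, d_mean, d_var = f[0]
        seg_z = (x[140:160] - np.median(x)) / sd
        d = np.diff(seg_z)
        assert d_mean == pytest.approx(d.mean(), abs=1e-12)
        assert d_mean == pytest.approx(-0.05 / sd, rel=1e-6)
        assert d_var == pytest.approx(0.0, abs=1e-12)

    def test_step_drop_min_max(self):
        x = np.full(300, 97.0)
        x[150:] = 93.0                               # single 4 % step
        s = SignalStream(x, 1.0)
        sd = np.std(x)
        _, f = spo2_features(s, SCHEME, np.array([120.0]))
        _, d_min, d_max, _, _ = f[0]
        assert d_min == pytest.approx(-4.0 / sd, rel=1e-9)
        assert d_max == pytest.approx(0.0, abs=1e-12)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            spo2_features(SignalStream(np.full(30, 97.0), 1.0), SCHEME)


class TestAssembleFrames:
    def make_streams(self, dur=600.0):
        fs = 50.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        eff = np.sin(2 * np.pi * 0.25 * t)
        amp = SignalStream(np.ones(n), fs)
        effs = SignalStream(eff, fs)
        spo2 = SignalStream(np.full(int(dur), 97.0) - 0.01 * np.arange(int(dur)),
                            1.0)
        return amp, effs, spo2

    def test_frame_count_and_spacing(self):
        amp, eff, spo2 = self.make_streams(600.0)
        frames = assemble_frames(amp, amp, eff, eff, spo2)
        # warm-up 60 s + 40-s SpO2 look-ahead: t in [60, 560]
        assert len(frames) == int((600 - 100) / 0.5) + 1
        dt = np.diff([f.t_s for f in frames])
        np.testing.assert_allclose(dt, 0.5)
        assert frames[0].t_s == 60.0
        assert len(frames[0].values()) == 9 == len(FEATURE_NAMES)

    def test_missing_spo2_rejected(self):
        amp, eff, _ = self.make_streams()
        with pytest.raises(ValueError, match="spo2"):
            assemble_frames(amp, amp, eff, eff, None)

    def test_misaligned_origin_rejected(self):
        amp, eff, spo2 = self.make_streams()
        shifted = SignalStream(amp.samples, amp.rate_hz, start_s=3.0)
        with pytest.raises(ValueError, match="origin"):
            assemble_frames(amp, shifted, eff, eff, spo2)
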