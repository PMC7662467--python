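"""Per-step features for breathing-event classification.

Nine features are computed on a 0.5-s frame grid:

* ``ar_tho``, ``ar_abd`` -- amplitude ratios: the 95 % quantile of the
  SST-estimated instantaneous amplitude over the current 10-s window (CW)
  divided by the same quantile over the previous 60-s window (PW). Near 1
  during normal breathing, ~0.7 during hypopnea, ~0 during central apnea.
* ``fr_tho``, ``fr_abd`` -- frequency ratios: log10 of spectral energy in
  the cardiac band (0.8-1.5 Hz) over the respiratory band (0.1-0.8 Hz) of
  the raw (unfiltered) effort window. Large when breathing is silent and
  only the cardiogenic ripple remains. Computed on the axis-selected signal
  *before* the 0.8-Hz low-pass, which would otherwise suppress the cardiac
  band.
* five SpO2 features: the whole-night-normalised saturation at the frame
  time (baseline) and min/max/mean/variance of the first difference over a
  20-s segment delayed 20 s past the frame, matching the physiological lag
  between an event and its desaturation.

Frames are emitted only where every window is available: after a 60-s
warm-up and up to 40 s (SpO2 delay + segment) before the end of the night.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq

from .core_io import SignalStream

logger = logging.getLogger("apneakit")

FR_FLOOR = -6.0
FR_CEIL = 6.0
CARDIAC_BAND_HZ = (0.8, 1.5)
RESP_BAND_HZ = (0.1, 0.8)

FEATURE_NAMES = ("ar_tho", "ar_abd", "fr_tho", "fr_abd",
                 "spo2_base", "spo2_d_min", "spo2_d_max",
                 "spo2_d_mean", "spo2_d_var")


@dataclass(frozen=True)
class WindowScheme:
    """Window lengths and steps of the feature extractor (seconds)."""

    cw_len_s: float = 10.0
    cw_step_s: float = 0.5
    pw_len_s: float = 60.0
    spo2_seg_s: float = 20.0
    spo2_delay_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("cw_len_s", "cw_step_s", "pw_len_s",
                     "spo2_seg_s", "spo2_delay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def frame_times(self, duration_s: float) -> np.ndarray:
        """Frame times t with a full PW behind and CW + delayed SpO2 segment
        ahead: t in [pw_len, duration - (delay + seg)] on the cw_step grid."""
        t0 = self.pw_len_s
        t1 = duration_s - (self.spo2_delay_s + self.spo2_seg_s)
        n = int(np.floor((t1 - t0) / self.cw_step_s)) + 1
        if n < 1:
            raise ValueError(
                f"recording of {duration_s:.0f} s too short for the window scheme")
        return t0 + self.cw_step_s * np.arange(n)


@dataclass(frozen=True)
class FeatureFrame:
    """The nine features at one 0.5-s step (frame time = CW start)."""

    t_s: float
    ar_tho: float
    ar_abd: float
    fr_tho: float
    fr_abd: float
    spo2_base: float
    spo2_d_min: float
    spo2_d_max: float
    spo2_d_mean: float
    spo2_d_var: float

    def __post_init__(self) -> None:
        if self.ar_tho < 0 or self.ar_abd < 0:
            raise ValueError("amplitude ratios must be nonnegative")
        if self.spo2_d_var < 0:
            raise ValueError("spo2_d_var must be nonnegative")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES])


def _q95(x: np.ndarray) -> float:
    return float(np.quantile(x, 0.95))


def amplitude_ratio(amp: SignalStream, scheme: WindowScheme, n: int) -> float:
    """AR(n) = Q95(amp over CW(n)) / Q95(amp over PW(n)), with a small
    floor on the denominator tied to the night-median amplitude."""
    t = scheme.pw_len_s + n * scheme.cw_step_s
    cw = amp.segment(t, t + scheme.cw_len_s)
    pw = amp.segment(t - scheme.pw_len_s, t)
    if cw.size < scheme.cw_len_s * amp.rate_hz or pw.size < scheme.pw_len_s * amp.rate_hz:
        raise ValueError(f"frame {n} lacks a full PW/CW in the amplitude stream")
    eps = 1e-8 * float(np.median(amp.samples))
    return _q95(cw) / max(_q95(pw), eps, 1e-300)


def amplitude_ratio_series(amp: SignalStream, scheme: WindowScheme,
                           times: np.ndarray) -> np.ndarray:
    """Vectorised :func:`amplitude_ratio` for all frame times."""
    fs = amp.rate_hz
    cw_n = int(round(scheme.cw_len_s * fs))
    pw_n = int(round(scheme.pw_len_s * fs))
    step = scheme.cw_step_s * fs
    starts = np.round((times - amp.start_s) * fs).astype(int)
    eps = max(1e-8 * float(np.median(amp.samples)), 1e-300)
    # windows share a common stride only if the step is an integer number of
    # samples; fall back to the scalar path otherwise
    if abs(step - round(step)) < 1e-9 and starts.size > 1:
        step = int(round(step))
        cw_view = sliding_window_view(amp.samples, cw_n)[starts]
        pw_view = sliding_window_view(amp.samples, pw_n)[starts - pw_n]
        q_cw = np.quantile(cw_view, 0.95, axis=1)
        q_pw = np.quantile(pw_view, 0.95, axis=1)
        return q_cw / np.maximum(q_pw, eps)
    return np.array([amplitude_ratio(amp, scheme, n) for n in range(times.size)])


def _band_energy(power: np.ndarray, freqs: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return np.trapezoid(power[..., mask], freqs[mask], axis=-1)


def frequency_ratio(effort: SignalStream, scheme: WindowScheme, n: int) -> float:
    """FR(n): log10 of cardiac-band over respiratory-band spectral energy of
    the rectangular-windowed 10-s CW."""
    if effort.rate_hz < 4.0:
        raise ValueError("frequency_ratio needs a rate of at least 4 Hz")
    t = scheme.pw_len_s + n * scheme.cw_step_s
    cw = effort.segment(t, t + scheme.cw_len_s)
    return float(_fr_from_segments(cw[None, :], effort.rate_hz)[0])


def _fr_from_segments(segs: np.ndarray, fs: float) -> np.ndarray:
    freqs = rfftfreq(segs.shape[-1], d=1.0 / fs)
    power = np.abs(rfft(segs, axis=-1)) ** 2
    num = _band_energy(power, freqs, CARDIAC_BAND_HZ)
    den = _band_energy(power, freqs, RESP_BAND_HZ)
    out = np.full(segs.shape[0], FR_FLOOR)
    ok = (num > 0) & (den > 0)
    out[ok] = np.log10(num[ok] / den[ok])
    out[(num > 0) & (den == 0)] = FR_CEIL
    return np.clip(out, FR_FLOOR, FR_CEIL)


def frequency_ratio_series(effort: SignalStream, scheme: WindowScheme,
                           times: np.ndarray) -> np.ndarray:
    fs = effort.rate_hz
    cw_n = int(round(scheme.cw_len_s * fs))
    starts = np.round((times - effort.start_s) * fs).astype(int)
    segs = sliding_window_view(effort.samples, cw_n)[starts]
    return _fr_from_segments(segs, fs)


def spo2_features(spo2: SignalStream, scheme: WindowScheme,
                  times: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """SpO2 features for each frame time.

    The whole-night trace is normalised (median / SD); for frame time t the
    delayed segment [t+delay, t+delay+seg) of the 1-Hz trace yields the
    min/max/mean/variance of its first difference, and the normalised value
    at t is the baseline. Returns ``(times, features[n, 5])`` in the order
    (base, d_min, d_max, d_mean, d_var).
    """
    if spo2.duration_s < 60.0:
        raise ValueError("spo2_features needs at least 60 s of SpO2")
    x = spo2.samples
    sd = float(np.std(x))
    if sd == 0.0:
        logger.warning("constant SpO2 trace; normalising with SD = 1")
        sd = 1.0
    z = (x - float(np.median(x))) / sd
    if times is None:
        times = scheme.frame_times(spo2.duration_s)
    fs = spo2.rate_hz
    seg_n = int(round(scheme.spo2_seg_s * fs))
    base_idx = np.floor((times - spo2.start_s) * fs).astype(int)
    seg_starts = np.floor((times - spo2.start_s + scheme.spo2_delay_s) * fs).astype(int)
    if seg_starts.max() + seg_n > z.size:
        raise ValueError("SpO2 trace too short for the delayed segments")
    d = np.diff(z) * fs                      # per-second first derivative
    dview = sliding_window_view(d, seg_n - 1)[seg_starts]
    feats = np.column_stack([
        z[base_idx],
        dview.min(axis=1),
        dview.max(axis=1),
        dview.mean(axis=1),
        dview.var(axis=1),
    ])
    return np.asarray(times, dtype=float), feats


def assemble_frames(tho_amp: SignalStream, abd_amp: SignalStream,
                    tho_eff: SignalStream, abd_eff: SignalStream,
                    spo2: SignalStream | None,
                    scheme: WindowScheme | None = None) -> list[FeatureFrame]:
    """Assemble one :class:`FeatureFrame` per 0.5-s step where all windows
    are available. SpO2 features (1 Hz) are sampled-and-held across the
    0.5-s frames they cover."""
    scheme = scheme or WindowScheme()
    if spo2 is None:
        raise ValueError("missing stream: spo2 (required for feature frames)")
    streams = {"tho_amp": tho_amp, "abd_amp": abd_amp,
               "tho_eff": tho_eff, "abd_eff": abd_eff, "spo2": spo2}
    origin = tho_amp.start_s
    for name, s in streams.items():
        if abs(s.start_s - origin) > 1e-9:
            raise ValueError(f"stream {name!r} origin {s.start_s} differs from "
                             f"{origin}; align streams before assembling")
    duration = min(s.duration_s for s in streams.values())
    times = scheme.frame_times(duration) + origin

    ar_tho = amplitude_ratio_series(tho_amp, scheme, times)
    ar_abd = amplitude_ratio_series(abd_amp, scheme, times)
    fr_tho = frequency_ratio_series(tho_eff, scheme, times)
    fr_abd = frequency_ratio_series(abd_eff, scheme, times)
    _, sp = spo2_features(spo2, scheme, times)

    return [
        FeatureFrame(t, at, aa, ft, fa, *row)
        for t, at, aa, ft, fa, row in zip(times, ar_tho, ar_abd,
                                          fr_tho, fr_abd, sp)
    ]


def frames_to_array(frames: list[FeatureFrame]) -> tuple[np.ndarray, np.ndarray]:
    """(times, X[n, 9]) view of a frame sequence."""
    t = np.array([f.t_s for f in frames])
    X = np.array([f.values() for f in frames])
    return t, X


def frames_to_dataframe(frames: list[FeatureFrame]):
    import pandas as pd

    t, X = frames_to_array(frames)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "t_s", t)
    return df
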