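"""Synchrosqueezing time-frequency analysis of respiratory effort.

The respiratory effort signal is modelled as a single amplitude- and
frequency-modulated oscillation A(t) sin(phi(t)). A continuous-wavelet
transform with an analytic Gaussian (Morlet-type) mother wavelet is
sharpened by synchrosqueezing: each wavelet coefficient is reassigned to
the frequency bin given by its own phase derivative. Summing the squeezed
transform across a small neighbourhood of the dominant ridge recovers the
instantaneous amplitude A(t) -- insensitive to DC shifts and to broadband
posture artifacts, which is exactly why it is used for the amplitude-ratio
features.

Implementation notes
--------------------
* Mother wavelet: psi_hat(xi) = exp(-(xi - MU)^2 / (2 SIGMA^2)) for xi > 0.
  SIGMA = 2.3 trades frequency resolution for a ~2-s time resolution so the
  amplitude estimate settles quickly after apneic amplitude steps.
* Scale/frequency grid: log-spaced, 32 voices per octave over 0.05-2 Hz.
* Amplitude normalisation: for a tone at grid frequency f, summing the CWT
  over scales with log-spacing dln(a) converges to (A/2) C(f) where
  C(f) = sum_k psi_hat(a_k * 2 pi f) dln(a); C is precomputed per grid bin,
  which also corrects for scale-grid truncation near the band edges.
* Ridge: maximum-energy path through the squeezed energy inside the
  requested band, with a quadratic penalty on log-frequency jumps
  (first-order dynamic programming).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import fft, ifft, next_fast_len

from .core_io import SignalStream

MORLET_MU = 6.0
MORLET_SIGMA = 2.3
VOICES_PER_OCTAVE = 32
FREQ_RANGE_HZ = (0.05, 2.0)
RESP_BAND_HZ = (0.1, 0.8)
EDGE_PAD_S = 15.0
RIDGE_PENALTY = 4.0          # lambda on squared log-frequency jumps
AMP_HALFWIDTH_BINS = 2       # +-Delta bins integrated around the ridge
_SST_WORK_RATE_HZ = 10.0     # internal analysis rate; band tops out at 2 Hz


@dataclass
class TfrResult:
    """Synchrosqueezed transform, ridge and instantaneous amplitude."""

    times: np.ndarray          # seconds, recording-relative
    freqs: np.ndarray          # Hz, log-spaced grid
    energy: np.ndarray         # (n_times, n_freqs), squeezed |T|^2
    ridge_hz: np.ndarray       # per-time dominant frequency in the band
    amp: np.ndarray            # per-time instantaneous amplitude

    def __post_init__(self) -> None:
        if np.any(self.energy < 0):
            raise ValueError("energy must be nonnegative")


def _wavelet_hat(xi: np.ndarray) -> np.ndarray:
    # the second term is the standard Morlet admissibility correction: it
    # forces psi_hat(0+) = 0 so near-DC energy (posture steps, drift)
    # cannot leak into every scale
    s2 = 2.0 * MORLET_SIGMA ** 2
    out = (np.exp(-((xi - MORLET_MU) ** 2) / s2)
           - np.exp(-MORLET_MU ** 2 / s2) * np.exp(-xi ** 2 / s2))
    return np.where(xi > 0, out, 0.0)


def _freq_grid() -> np.ndarray:
    lo, hi = FREQ_RANGE_HZ
    n = int(np.ceil(np.log2(hi / lo) * VOICES_PER_OCTAVE)) + 1
    return lo * 2.0 ** (np.arange(n) / VOICES_PER_OCTAVE)


def sst(stream: SignalStream, band_hz: tuple[float, float]) -> TfrResult:
    """Synchrosqueezed transform with ridge/amplitude extraction in ``band_hz``."""
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ValueError(f"band ({lo}, {hi}) is empty or inverted")
    if hi >= stream.rate_hz / 2:
        raise ValueError(f"band upper edge {hi} Hz at or above Nyquist")
    if stream.duration_s < 30.0:
        raise ValueError("sst needs at least 30 s of signal")

    fs = stream.rate_hz
    x = np.asarray(stream.samples, dtype=float)
    pad = int(round(EDGE_PAD_S * fs))
    pad = min(pad, x.size - 1)
    xp = np.pad(x, pad, mode="reflect")
    n = xp.size
    nfft = next_fast_len(n)
    X = fft(xp, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)

    freqs = _freq_grid()
    nb = freqs.size
    dln = np.log(2.0) / VOICES_PER_OCTAVE
    scales = MORLET_MU / (2.0 * np.pi * freqs)

    # CWT rows and their time derivative, evaluated via the FFT
    W = np.empty((nb, n), dtype=complex)
    dW = np.empty((nb, n), dtype=complex)
    for k, a in enumerate(scales):
        H = _wavelet_hat(a * omega)
        W[k] = ifft(X * H, nfft)[:n]
        dW[k] = ifft(X * H * (1j * omega), nfft)[:n]

    absW = np.abs(W)
    wmax = absW.max()
    T = np.zeros((nb, n), dtype=complex)
    if wmax > 0:
        gamma = 1e-6 * wmax
        with np.errstate(divide="ignore", invalid="ignore"):
            f_inst = np.imag(dW / W) / (2.0 * np.pi)
        valid = (absW > gamma) & np.isfinite(f_inst) & (f_inst > 0)
        f_safe = np.where(valid, f_inst, 1.0)
        idx = np.round(np.log(f_safe / freqs[0]) / dln).astype(np.int64)
        valid &= (idx >= 0) & (idx < nb)
        tgrid = np.broadcast_to(np.arange(n), (nb, n))
        flat = idx[valid] * n + tgrid[valid]
        w = W[valid] * dln
        size = nb * n
        T = (np.bincount(flat, weights=w.real, minlength=size)
             + 1j * np.bincount(flat, weights=w.imag, minlength=size)
             ).reshape(nb, n)

    T = T[:, pad:pad + x.size]
    E = np.abs(T) ** 2

    band_rows = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if band_rows.size == 0:
        raise ValueError(f"band ({lo}, {hi}) contains no grid frequencies")
    ridge_rows = _ridge(E[band_rows], np.log(freqs[band_rows]))
    ridge_idx = band_rows[ridge_rows]
    ridge_hz = freqs[ridge_idx]

    # normalisation constant per potential ridge bin (corrects truncation)
    arg = scales[:, None] * (2.0 * np.pi * freqs[None, :])
    C = _wavelet_hat(arg).sum(axis=0) * dln

    nt = x.size
    amp = np.empty(nt)
    lo_b = np.maximum(ridge_idx - AMP_HALFWIDTH_BINS, 0)
    hi_b = np.minimum(ridge_idx + AMP_HALFWIDTH_BINS, nb - 1)
    csum = np.concatenate([np.zeros((1, nt), dtype=complex), np.cumsum(T, axis=0)])
    cols = np.arange(nt)
    seg = csum[hi_b + 1, cols] - csum[lo_b, cols]
    amp = 2.0 * np.abs(seg) / C[ridge_idx]

    return TfrResult(times=stream.times, freqs=freqs, energy=E.T,
                     ridge_hz=ridge_hz, amp=amp)


def _ridge(E: np.ndarray, logf: np.ndarray) -> np.ndarray:
    """Max-energy path through (n_band, n_times) energy with a quadratic
    log-frequency jump penalty (Viterbi)."""
    nbb, nt = E.shape
    score = np.log(E + 1e-300)
    pen = RIDGE_PENALTY * (logf[:, None] - logf[None, :]) ** 2
    acc = score[:, 0].copy()
    back = np.empty((nt, nbb), dtype=np.int32)
    for t in range(1, nt):
        tot = acc[:, None] - pen            # (prev, cur)
        best = np.argmax(tot, axis=0)
        back[t] = best
        acc = tot[best, np.arange(nbb)] + score[:, t]
    path = np.empty(nt, dtype=np.int32)
    path[-1] = int(np.argmax(acc))
    for t in range(nt - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def instantaneous_amplitude(stream: SignalStream,
                            band_hz: tuple[float, float] = RESP_BAND_HZ
                            ) -> SignalStream:
    """Instantaneous amplitude of the respiratory oscillation, on the
    signal's own time grid.

    Signals sampled well above the analysis band are decimated to 10 Hz for
    the transform and the amplitude is linearly interpolated back, which
    changes nothing inside the 0.1-0.8 Hz band but keeps the transform cheap.
    """
    fs = stream.rate_hz
    if fs > 1.25 * _SST_WORK_RATE_HZ:
        down = int(round(fs / _SST_WORK_RATE_HZ))
        y = sps.resample_poly(stream.samples, up=1, down=down)
        work = SignalStream(y, fs / down, stream.start_s, stream.label)
        res = sst(work, band_hz)
        amp = np.interp(stream.times, res.times, res.amp)
    else:
        res = sst(stream, band_hz)
        amp = res.amp
    return SignalStream(np.maximum(amp, 0.0), fs, stream.start_s, stream.label)
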