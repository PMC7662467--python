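"""Triaxial acceleration -> 1-D respiratory effort.

Each accelerometer placement yields three axes; only one carries the
respiratory excursion at any given posture. Axis selection counts breathing
peaks in 30-s segments advancing every 10 s, picks per segment the axis whose
count is closest to the physiological 6-9 breaths / 30 s band, and outputs
the modal axis of the five most recent segments (ties broken by larger RMS).
The selected 1-D signal is then low-pass filtered (6th-order Butterworth,
0.8 Hz, zero-phase).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .core_io import SignalStream, TriaxialStream

LOWPASS_CUTOFF_HZ = 0.8
LOWPASS_ORDER = 6
SEGMENT_S = 30.0
STEP_S = 10.0
VOTE_LEN = 5
BREATH_BAND = (6, 9)          # acceptable peaks per 30-s segment
PEAK_MIN_SEPARATION_S = 2.0
PEAK_PROMINENCE_FRAC = 0.25   # of the segment standard deviation

_AXES = ("x", "y", "z")


@dataclass
class AxisTrace:
    """Per-step bookkeeping of the axis-selection vote (debug/export)."""

    segment_index: list[int] = field(default_factory=list)
    peak_counts: list[dict[str, int]] = field(default_factory=list)
    selected_axis: list[str] = field(default_factory=list)
    final_axis: list[str] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "segment_index": self.segment_index,
            **{f"peaks_{a}": [c[a] for c in self.peak_counts] for a in _AXES},
            "selected_axis": self.selected_axis,
            "final_axis": self.final_axis,
        })


def lowpass_respiratory(stream: SignalStream) -> SignalStream:
    """6th-order 0.8-Hz Butterworth low-pass, applied forward-backward."""
    if stream.rate_hz <= 2 * LOWPASS_CUTOFF_HZ:
        raise ValueError(
            f"rate {stream.rate_hz} Hz is at or below twice the "
            f"{LOWPASS_CUTOFF_HZ}-Hz cutoff; cannot filter")
    sos = sps.butter(LOWPASS_ORDER, LOWPASS_CUTOFF_HZ, btype="low",
                     fs=stream.rate_hz, output="sos")
    y = sps.sosfiltfilt(sos, stream.samples)
    return SignalStream(y, stream.rate_hz, stream.start_s, stream.label)


def count_breath_peaks(segment: np.ndarray, rate_hz: float) -> int:
    """Count accepted breathing maxima in one segment.

    The segment is first smoothed with a 1-s moving average (breaths at
    0.2-0.3 Hz pass nearly untouched, broadband sensor noise is attenuated
    by ~sqrt(rate)); a maximum is then accepted if its prominence is at
    least a quarter of the smoothed segment's standard deviation and it is
    separated from its neighbours by at least 2 s, which caps the count
    near 15 per 30 s, well above the 6-9 target band.
    """
    x = np.asarray(segment, dtype=float)
    w = max(int(round(rate_hz)), 1)
    if w > 1:
        x = uniform_filter1d(x, w, mode="nearest")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0
    peaks, _ = sps.find_peaks(x, prominence=PEAK_PROMINENCE_FRAC * sd,
                              distance=max(int(PEAK_MIN_SEPARATION_S * rate_hz), 1))
    return int(peaks.size)


def _band_distance(count: int) -> float:
    lo, hi = BREATH_BAND
    if lo <= count <= hi:
        return 0.0
    return min(abs(count - lo), abs(count - hi))


def select_axis(triax: TriaxialStream, lowpass: bool = True
                ) -> tuple[SignalStream, AxisTrace]:
    """Fuse a triaxial stream into a single respiratory effort signal.

    The output covers the full input length: 10-s spans are copied from the
    axis winning the 5-segment majority vote; the first four steps (before
    the first complete vote) reuse the first completed vote, and trailing
    spans beyond the last complete 30-s segment reuse the final vote.
    """
    fs = triax.rate_hz
    n = len(triax.x)
    seg_len = int(round(SEGMENT_S * fs))
    step_len = int(round(STEP_S * fs))
    n_seg = (n - seg_len) // step_len + 1
    if n_seg < VOTE_LEN:
        raise ValueError(
            f"axis selection needs at least {int((VOTE_LEN - 1) * STEP_S + SEGMENT_S)} s "
            f"of signal ({VOTE_LEN} overlapping 30-s segments); got {n / fs:.0f} s")

    mat = triax.as_matrix()                       # (n, 3)
    counts = np.empty((n_seg, 3), dtype=int)
    rms = np.empty((n_seg, 3))
    for k in range(n_seg):
        seg = mat[k * step_len:k * step_len + seg_len]
        for j in range(3):
            counts[k, j] = count_breath_peaks(seg[:, j], fs)
        rms[k] = np.sqrt(np.mean(seg ** 2, axis=0))

    # per-segment choice: count nearest the 6-9 band, RMS breaks ties
    chosen = np.empty(n_seg, dtype=int)
    for k in range(n_seg):
        d = np.array([_band_distance(c) for c in counts[k]])
        best = np.flatnonzero(d == d.min())
        chosen[k] = best[np.argmax(rms[k, best])]

    # five-segment majority vote; ties by larger RMS over the voting segments
    trace = AxisTrace()
    votes = np.empty(n_seg, dtype=int)
    for k in range(n_seg):
        w0 = max(k - VOTE_LEN + 1, 0)
        if k < VOTE_LEN - 1:
            votes[k] = -1                          # filled from first full vote
            continue
        window = chosen[w0:k + 1]
        tally = np.bincount(window, minlength=3)
        top = np.flatnonzero(tally == tally.max())
        if top.size == 1:
            votes[k] = top[0]
        else:
            vote_rms = np.sqrt(np.mean(rms[w0:k + 1, top] ** 2, axis=0))
            votes[k] = top[np.argmax(vote_rms)]
    votes[:VOTE_LEN - 1] = votes[VOTE_LEN - 1]

    for k in range(n_seg):
        trace.segment_index.append(k)
        trace.peak_counts.append({a: int(counts[k, j]) for j, a in enumerate(_AXES)})
        trace.selected_axis.append(_AXES[chosen[k]])
        trace.final_axis.append(_AXES[votes[k]])

    # assemble: 10-s span k (= samples [k*step, (k+1)*step)) from vote k,
    # clipped to the last complete segment for the tail
    n_span = int(np.ceil(n / step_len))
    out = np.empty(n)
    for k in range(n_span):
        v = votes[min(k, n_seg - 1)]
        sl = slice(k * step_len, min((k + 1) * step_len, n))
        out[sl] = mat[sl, v]

    stream = SignalStream(out, fs, triax.start_s,
                          "tho" if triax.placement == "thoracic" else "abd")
    if lowpass:
        stream = lowpass_respiratory(stream)
    return stream, trace
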