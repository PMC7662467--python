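"""End-to-end scoring chain: recording -> features -> classifier -> fusion
-> events -> AHI report. Shared by the CLI and the training helpers."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import HYPNO_EPOCH_S, HypnoEpoch, Recording, SleepState
from .features import FEATURE_NAMES, WindowScheme, assemble_frames, frames_to_array
from .models import (EventModel, ProbSeries, SleepWakeConfig, SleepWakeModel,
                     delayed_spo2, ihr, predict_event_probs, predict_sleepwake,
                     sleepwake_windows)
from .preprocess import select_axis
from .scoring import (DesatMark, compute_ahi, detect_desaturation,
                      extract_events, fuse, rasterize_events)
from .tfa import instantaneous_amplitude


def night_frames(rec: Recording, scheme: WindowScheme | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessing + feature extraction for one night: axis selection on
    both accelerometer placements, SST instantaneous amplitudes, and the
    nine-feature frames. Returns ``(frame_times, X[n, 9])``.

    The frequency-ratio features use the axis-selected signal before the
    0.8-Hz low-pass so the cardiogenic 0.8-1.5 Hz band survives.
    """
    scheme = scheme or WindowScheme()
    tho_raw, _ = select_axis(rec.tho_taa, lowpass=False)
    abd_raw, _ = select_axis(rec.abd_taa, lowpass=False)
    tho_amp = instantaneous_amplitude(tho_raw)
    abd_amp = instantaneous_amplitude(abd_raw)
    frames = assemble_frames(tho_amp, abd_amp, tho_raw, abd_raw,
                             rec.spo2, scheme)
    return frames_to_array(frames)


def frames_dataframe(times: np.ndarray, X: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "t_s", times)
    return df


def all_sleep_hypnogram(duration_s: float) -> list[HypnoEpoch]:
    n = int(duration_s // HYPNO_EPOCH_S)
    return [HypnoEpoch(i * HYPNO_EPOCH_S, SleepState.SLEEP) for i in range(n)]


@dataclass
class ScoreResult:
    """Everything the scoring chain produced for one night."""

    report: object                # AhiReport
    probs: ProbSeries
    labels: np.ndarray            # fused per-step class codes
    hypnogram: list[HypnoEpoch]
    desat: DesatMark | None
    frame_times: np.ndarray


def score_recording(rec: Recording, event_model: EventModel,
                    sleepwake_model: SleepWakeModel | None = None,
                    scheme: WindowScheme | None = None,
                    use_desat: bool = True,
                    use_sleepwake: bool = True) -> ScoreResult:
    """Score one recording into an AHI report.

    With ``use_sleepwake=False`` every epoch is treated as sleep (total
    sleep time = recording length); with ``use_desat=False`` the
    desaturation-rescue of NOR steps is disabled.
    """
    scheme = scheme or WindowScheme()
    times, X = night_frames(rec, scheme)
    probs = predict_event_probs(event_model, frames_dataframe(times, X),
                                align="center")
    desat = detect_desaturation(rec.spo2) if use_desat else None
    if use_sleepwake:
        if sleepwake_model is None:
            raise ValueError("sleep-wake scoring requested but no model given")
        hypno = predict_sleepwake(sleepwake_model, rec)
    else:
        hypno = all_sleep_hypnogram(rec.duration_s)
    labels = fuse(probs, desat, hypno)
    events = extract_events(labels, scheme.cw_step_s, t0=float(times[0]))
    report = compute_ahi(events, hypno)
    return ScoreResult(report, probs, labels, hypno, desat, times)


def event_windows_from_recording(rec: Recording, scheme: WindowScheme | None = None,
                                 window_frames: int = 40, window_step: int = 5
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled LSTM training windows from an annotated recording: windows
    slide ``window_step`` frames apart; each takes the majority expert label
    over its span (labels sampled at the 10-s current-window centres).
    Returns ``(windows, labels, near_event)`` where ``near_event`` flags
    windows whose centre lies within 60 s of a scored event -- the hard
    negatives a balanced training set must keep."""
    if rec.events is None:
        raise ValueError("recording has no event annotations")
    times, X = night_frames(rec, scheme)
    lab = rasterize_events(rec.events, times + 5.0)
    win_idx = np.arange(window_frames - 1, X.shape[0], window_step)
    windows = np.lib.stride_tricks.sliding_window_view(
        X, window_frames, axis=0).transpose(0, 2, 1)[win_idx - window_frames + 1]
    wlab = np.array([np.bincount(lab[j - window_frames + 1:j + 1],
                                 minlength=4).argmax() for j in win_idx])
    centre_t = times[win_idx] - (window_frames - 1) * 0.25
    near = np.zeros(win_idx.size, dtype=bool)
    for ev in rec.events:
        near |= (centre_t > ev.start_s - 60.0) & (centre_t < ev.end_s + 60.0)
    return np.ascontiguousarray(windows), wlab, near


def sleepwake_windows_from_recording(rec: Recording,
                                     sw_cfg: SleepWakeConfig | None = None
                                     ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled CNN training windows (one per 30-s epoch) from an annotated
    recording; R peaks are taken from the recording when present."""
    if rec.hypnogram is None:
        raise ValueError("recording has no hypnogram annotations")
    sw_cfg = sw_cfg or SleepWakeConfig()
    if rec.r_peaks is not None and len(rec.r_peaks) >= 2:
        r_peaks = rec.r_peaks
    else:
        from .models import detect_r_peaks

        r_peaks = detect_r_peaks(rec.ecg)
    hr_stream = ihr(r_peaks, grid_end_s=rec.duration_s)
    hr = np.interp(np.arange(rec.duration_s), hr_stream.times, hr_stream.samples)
    sp = delayed_spo2(rec.spo2, sw_cfg.spo2_delay_s)
    n_ep = len(rec.hypnogram)
    X = sleepwake_windows(hr, sp, n_ep, sw_cfg)
    y = np.array([e.state == SleepState.WAKE for e in rec.hypnogram], dtype=int)
    return X, y
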