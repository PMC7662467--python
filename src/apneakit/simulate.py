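"""Synthetic overnight recordings with scripted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* quasi-periodic respiratory effort (slowly drifting rate inside 0.2-0.3 Hz,
  6-9 breaths per 30 s) projected onto one accelerometer axis per posture
  state, with white sensor noise on all axes;
* OSA: effort continues -- envelopes rise to ~1.4x baseline (crescendo
  effort against the occlusion) while thorax and abdomen drift to antiphase,
  so the airflow-equivalent THO+ABD sum collapses by over 90 %;
* CSA: both envelopes fall to ~3 % of baseline and a ~1.1-Hz cardiogenic
  ripple becomes visible;
* HYP: both envelopes reduced to 70 % of baseline (a 30 % reduction);
* every scripted event schedules a >=3 % SpO2 desaturation, delayed
  19.3 +- 9.6 s after event onset (truncated at 5 s), linear 10-s decline
  and exponential recovery (tau = 15 s); event durations are
  20.2 +- 3.4 s truncated at the 10-s scoring minimum;
* ECG rendered at 500 Hz from an RR process whose mean and variability rise
  during wake bouts; wake bouts carry no scored events.

Everything is driven by ``SimConfig.seed``; the same seed reproduces the
recording sample-for-sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_io import (ABNORMAL_KINDS, EventInterval, EventKind, HypnoEpoch,
                      Recording, SignalStream, SleepState, TriaxialStream)
from .models import SleepWakeConfig
from .pipeline import (event_windows_from_recording,
                       sleepwake_windows_from_recording)
from .scoring import compute_ahi

_EVENT_GAIN = {EventKind.OSA: 1.4, EventKind.CSA: 0.03, EventKind.HYP: 0.7}


@dataclass(frozen=True)
class SimConfig:
    """Scripted statistics of one synthetic night."""

    duration_h: float = 0.5
    seed: int = 0
    event_rate_per_h: Mapping[EventKind, float] = field(
        default_factory=lambda: {EventKind.OSA: 8.0, EventKind.CSA: 5.0,
                                 EventKind.HYP: 7.0})
    event_duration_mean_s: float = 20.2
    event_duration_sd_s: float = 3.4
    event_duration_min_s: float = 10.0
    desat_delay_mean_s: float = 19.3
    desat_delay_sd_s: float = 9.6
    desat_delay_min_s: float = 5.0
    desat_depth_pct: tuple[float, float] = (3.5, 8.0)
    breath_hz: tuple[float, float] = (0.2, 0.3)
    posture_change_rate_per_h: float = 2.0
    wake_bouts: int = 1
    wake_bout_len_s: tuple[float, float] = (120.0, 300.0)
    cardiogenic_amp: float = 0.03
    cardiogenic_hz: float = 1.1
    noise_sd: float = 0.05
    taa_rate_hz: float = 50.0
    spo2_rate_hz: float = 1.0
    ecg_rate_hz: float = 500.0
    min_event_gap_s: float = 70.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.event_rate_per_h.values()):
            raise ValueError("event rates must be nonnegative")
        if self.desat_depth_pct[0] <= 3.0:
            raise ValueError("scripted desaturation depths must exceed 3 %")


def _smooth_drift(rng: np.random.Generator, n: int, fs: float,
                  sd: float, corr_s: float = 120.0) -> np.ndarray:
    """Zero-mean slowly varying Gaussian drift with the given pointwise SD."""
    raw = rng.standard_normal(n)
    sm = gaussian_filter1d(raw, corr_s * fs, mode="reflect")
    s = sm.std()
    return sm / s * sd if s > 0 else np.zeros(n)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, size: int) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        v = rng.normal(mean, sd)
        while v < lo:
            v = rng.normal(mean, sd)
        out[i] = v
    return out


def _place_wake_bouts(cfg: SimConfig, rng: np.random.Generator,
                      n_epochs: int) -> np.ndarray:
    """Boolean wake flag per 30-s epoch."""
    wake = np.zeros(n_epochs, dtype=bool)
    for _ in range(cfg.wake_bouts):
        lo, hi = cfg.wake_bout_len_s
        n_ep = max(int(round(rng.uniform(lo, hi) / 30.0)), 1)
        for _ in range(200):
            s = int(rng.integers(1, max(n_epochs - n_ep - 1, 2)))
            if not wake[max(s - 1, 0):s + n_ep + 1].any():
                wake[s:s + n_ep] = True
                break
    return wake


def _place_events(cfg: SimConfig, rng: np.random.Generator, dur_s: float,
                  wake_epochs: np.ndarray, tst_h: float) -> list[EventInterval]:
    kinds: list[EventKind] = []
    for kind in ABNORMAL_KINDS:
        kinds += [kind] * int(round(cfg.event_rate_per_h.get(kind, 0.0) * tst_h))
    rng.shuffle(kinds)
    durations = _truncated_normal(rng, cfg.event_duration_mean_s,
                                  cfg.event_duration_sd_s,
                                  cfg.event_duration_min_s, len(kinds))
    wake_spans = [(30.0 * i, 30.0 * (i + 1))
                  for i in np.flatnonzero(wake_epochs)]
    placed: list[EventInterval] = []
    for kind, d in zip(kinds, durations):
        ok = False
        for _ in range(5000):
            t0 = rng.uniform(60.0, dur_s - 120.0 - d)
            t1 = t0 + d
            if any(t0 - 5 < we and t1 + 5 > ws for ws, we in wake_spans):
                continue
            if any(t0 - cfg.min_event_gap_s < ev.end_s
                   and t1 + cfg.min_event_gap_s > ev.start_s for ev in placed):
                continue
            placed.append(EventInterval(t0, t1, kind))
            ok = True
            break
        if not ok:
            raise ValueError(
                f"event load ({len(kinds)} events) exceeds the "
                f"{dur_s / 3600:.2f}-h night with a {cfg.min_event_gap_s}-s gap")
    return sorted(placed, key=lambda e: e.start_s)


def _event_profile(events: Sequence[EventInterval], t: np.ndarray,
                   fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample envelope gain, abdominal phase offset and CSA indicator,
    smoothed over ~2-s transitions."""
    gain = np.ones(t.size)
    phase_off = np.zeros(t.size)
    csa = np.zeros(t.size)
    for ev in events:
        sl = slice(int(ev.start_s * fs), int(ev.end_s * fs))
        gain[sl] = _EVENT_GAIN[ev.kind]
        if ev.kind == EventKind.OSA:
            phase_off[sl] = np.pi
        if ev.kind == EventKind.CSA:
            csa[sl] = 1.0
    sig = fs * 1.0
    return (gaussian_filter1d(gain, sig), gaussian_filter1d(phase_off, sig),
            gaussian_filter1d(csa, sig))


def _spo2_trace(cfg: SimConfig, rng: np.random.Generator, dur_s: int,
                events: Sequence[EventInterval]
                ) -> tuple[np.ndarray, np.ndarray]:
    """1-Hz SpO2 with one scripted desaturation per event; returns the trace
    and the desaturation onset times."""
    t = np.arange(dur_s, dtype=float)
    base = 96.5 + 0.3 * np.sin(2 * np.pi * t / 900.0 + rng.uniform(0, 2 * np.pi))
    dips = np.zeros(dur_s)
    onsets = []
    for ev in events:
        delay = _truncated_normal(rng, cfg.desat_delay_mean_s,
                                  cfg.desat_delay_sd_s,
                                  cfg.desat_delay_min_s, 1)[0]
        depth = rng.uniform(*cfg.desat_depth_pct)
        start = ev.start_s + delay
        onsets.append(start)
        rel = t - start
        shape = np.zeros(dur_s)
        decline = (rel >= 0) & (rel < 10)
        shape[decline] = rel[decline] / 10.0
        rec = rel >= 10
        shape[rec] = np.exp(-(rel[rec] - 10.0) / 15.0)
        dips -= depth * shape
    return base + dips, np.array(onsets)


def _rr_process(cfg: SimConfig, rng: np.random.Generator, dur_s: float,
                wake_epochs: np.ndarray) -> np.ndarray:
    """R-peak times from a state-dependent AR(1) RR process."""
    peaks = [float(rng.uniform(0.2, 0.8))]
    v = 0.0
    while peaks[-1] < dur_s:
        ep = min(int(peaks[-1] // 30), wake_epochs.size - 1)
        wake = bool(wake_epochs[ep])
        mean = 0.75 if wake else 1.0
        sd = 0.06 if wake else 0.025
        v = 0.9 * v + sd * rng.standard_normal()
        rr = float(np.clip(mean + v, 0.35, 2.0))
        peaks.append(peaks[-1] + rr)
    return np.array(peaks[:-1])


def _render_ecg(cfg: SimConfig, rng: np.random.Generator, dur_s: int,
                r_peaks: np.ndarray) -> np.ndarray:
    fs = cfg.ecg_rate_hz
    n = int(dur_s * fs)
    tpl_t = np.arange(-0.06, 0.06, 1.0 / fs)
    tpl = (np.exp(-0.5 * (tpl_t / 0.012) ** 2)
           - 0.15 * np.exp(-0.5 * ((tpl_t - 0.04) / 0.015) ** 2)
           - 0.15 * np.exp(-0.5 * ((tpl_t + 0.04) / 0.015) ** 2))
    ecg = 0.01 * rng.standard_normal(n)
    ecg += 0.05 * np.sin(2 * np.pi * 0.3 * np.arange(n) / fs)
    half = tpl.size // 2
    for rp in r_peaks:
        c = int(round(rp * fs))
        lo, hi = c - half, c - half + tpl.size
        if lo >= 0 and hi <= n:
            ecg[lo:hi] += tpl
    return ecg


def _posture_segments(cfg: SimConfig, rng: np.random.Generator,
                      dur_s: float) -> list[tuple[float, float, int, np.ndarray]]:
    """(t0, t1, dominant_axis, projection_vector) per posture state."""
    changes = [0.0]
    rate = cfg.posture_change_rate_per_h / 3600.0
    t = 0.0
    while rate > 0:
        t += rng.exponential(1.0 / rate)
        if t >= dur_s:
            break
        changes.append(t)
    changes.append(dur_s)
    segs = []
    prev_axis = -1
    for t0, t1 in zip(changes[:-1], changes[1:]):
        axis = int(rng.integers(0, 3))
        if axis == prev_axis:
            axis = (axis + 1) % 3
        u = rng.normal(0, 0.12, size=3)
        u[axis] = rng.uniform(0.85, 1.0) * rng.choice([-1.0, 1.0])
        u /= np.linalg.norm(u)
        segs.append((t0, t1, axis, u))
        prev_axis = axis
    return segs


def generate_recording(cfg: SimConfig, return_details: bool = False):
    """Generate one labelled synthetic night.

    Returns ``(recording, truth_report)``; with ``return_details=True`` a
    third dict carries simulator internals (posture segments, desaturation
    onsets, respiratory rate trace) for targeted tests.
    """
    rng = np.random.default_rng(cfg.seed)
    dur_s = int(cfg.duration_h * 3600 // 30 * 30)
    n_epochs = dur_s // 30
    fs = cfg.taa_rate_hz

    wake_epochs = _place_wake_bouts(cfg, rng, n_epochs)
    hypnogram = [HypnoEpoch(30.0 * i,
                            SleepState.WAKE if wake_epochs[i] else SleepState.SLEEP)
                 for i in range(n_epochs)]
    tst_h = float(np.sum(~wake_epochs)) * 30.0 / 3600.0
    events = _place_events(cfg, rng, dur_s, wake_epochs, tst_h)

    n = int(dur_s * fs)
    t = np.arange(n) / fs
    lo, hi = cfg.breath_hz
    f = np.clip((lo + hi) / 2 + _smooth_drift(rng, n, fs, (hi - lo) / 4),
                lo, hi)
    phase = 2 * np.pi * np.cumsum(f) / fs
    A = np.clip(1.0 + _smooth_drift(rng, n, fs, 0.06, corr_s=60.0), 0.7, 1.3)
    gain, phase_off, csa = _event_profile(events, t, fs)
    card_phase = rng.uniform(0, 2 * np.pi)
    cardiogenic = (cfg.cardiogenic_amp * csa
                   * np.sin(2 * np.pi * cfg.cardiogenic_hz * t + card_phase))
    tho_eff = A * gain * np.sin(phase) + cardiogenic
    abd_eff = A * gain * np.sin(phase + 0.2 + phase_off) + cardiogenic

    segs = _posture_segments(cfg, rng, dur_s)

    def project(eff: np.ndarray, prefix: str) -> TriaxialStream:
        axes = cfg.noise_sd * rng.standard_normal((n, 3))
        for t0, t1, _, u in segs:
            sl = slice(int(t0 * fs), int(t1 * fs))
            axes[sl] += eff[sl, None] * u[None, :]
        streams = [SignalStream(axes[:, j], fs, 0.0, f"{prefix}_{a}")
                   for j, a in enumerate("xyz")]
        return TriaxialStream(*streams,
                              "thoracic" if prefix == "tho" else "abdominal")

    tho_taa = project(tho_eff, "tho")
    abd_taa = project(abd_eff, "abd")

    spo2, desat_onsets = _spo2_trace(cfg, rng, dur_s, events)
    r_peaks = _rr_process(cfg, rng, dur_s, wake_epochs)
    ecg = _render_ecg(cfg, rng, dur_s, r_peaks)

    rec = Recording(
        tho_taa=tho_taa, abd_taa=abd_taa,
        spo2=SignalStream(spo2, cfg.spo2_rate_hz, 0.0, "spo2"),
        ecg=SignalStream(ecg, cfg.ecg_rate_hz, 0.0, "ecg"),
        r_peaks=r_peaks, events=events, hypnogram=hypnogram)
    truth = compute_ahi(events, hypnogram)
    if return_details:
        details = {"posture_segments": segs, "desat_onsets": desat_onsets,
                   "breath_hz": f, "wake_epochs": wake_epochs}
        return rec, truth, details
    return rec, truth


# ---------------------------------------------------------------------------
# Training-set construction


@dataclass
class TrainingSet:
    """Windowed, labelled data from a set of simulated nights with a
    subject-disjoint train/test split (night index = subject)."""

    X_event: np.ndarray          # (n, frames, 9)
    y_event: np.ndarray          # class codes, NOR..HYP
    night_event: np.ndarray      # night id per window
    X_sleep: np.ndarray          # (n, 2, 300)
    y_sleep: np.ndarray          # 0 sleep / 1 wake
    night_sleep: np.ndarray
    train_nights: list[int]
    test_nights: list[int]

    def split(self, which: str):
        ids = self.train_nights if which == "train" else self.test_nights
        me = np.isin(self.night_event, ids)
        ms = np.isin(self.night_sleep, ids)
        return ((self.X_event[me], self.y_event[me]),
                (self.X_sleep[ms], self.y_sleep[ms]))


def make_training_set(cfg: SimConfig | Sequence[SimConfig], n_nights: int,
                      seed: int = 0, window_frames: int = 40,
                      window_step: int = 5, balance: bool = True,
                      sw_cfg: SleepWakeConfig | None = None) -> TrainingSet:
    """Simulate ``n_nights`` nights, run the feature chain and window the
    result for both classifiers.

    Event windows slide ``window_step`` frames apart and take the majority
    ground-truth label over the window; with ``balance`` the dominant NOR
    windows are subsampled to the mean abnormal-class count. The last third
    of the nights (at least one) forms the held-out test set.
    """
    if n_nights < 2:
        raise ValueError("need at least 2 nights for a subject-disjoint split")
    sw_cfg = sw_cfg or SleepWakeConfig()
    cfgs = (list(cfg) if isinstance(cfg, (list, tuple))
            else [replace(cfg, seed=seed + 7919 * i) for i in range(n_nights)])
    rng = np.random.default_rng(seed)
    Xe, ye, ne, near_all, Xs, ys, ns_ = [], [], [], [], [], [], []
    for night, c in enumerate(cfgs[:n_nights]):
        rec, truth = generate_recording(c)
        windows, wlab, near = event_windows_from_recording(
            rec, window_frames=window_frames, window_step=window_step)
        Xe.append(windows)
        ye.append(wlab)
        ne.append(np.full(wlab.size, night))
        near_all.append(near)
        Xsw, ysw = sleepwake_windows_from_recording(rec, sw_cfg)
        Xs.append(Xsw)
        ys.append(ysw)
        ns_.append(np.full(ysw.size, night))

    X_event = np.concatenate(Xe)
    y_event = np.concatenate(ye)
    night_event = np.concatenate(ne)
    if balance:
        # keep every abnormal window and every NOR window near an event
        # (hard negatives: they see the delayed desaturation with a normal
        # amplitude ratio); subsample only the far-from-event NOR windows
        near_event = np.concatenate(near_all)
        keep = np.ones(y_event.size, dtype=bool)
        far_nor = np.flatnonzero((y_event == 0) & ~near_event)
        abn_counts = [np.sum(y_event == c) for c in (1, 2, 3) if np.any(y_event == c)]
        target = int(np.mean(abn_counts)) if abn_counts else far_nor.size
        if far_nor.size > target:
            drop = rng.choice(far_nor, size=far_nor.size - target, replace=False)
            keep[drop] = False
        X_event, y_event, night_event = (X_event[keep], y_event[keep],
                                         night_event[keep])

    n_test = max(n_nights // 3, 1)
    nights = list(range(n_nights))
    return TrainingSet(
        X_event=X_event, y_event=y_event, night_event=night_event,
        X_sleep=np.concatenate(Xs), y_sleep=np.concatenate(ys),
        night_sleep=np.concatenate(ns_),
        train_nights=nights[:-n_test], test_nights=nights[-n_test:])
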