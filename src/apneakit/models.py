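"""Event classifier (LSTM), sleep-wake classifier (CNN), R-peaks and IHR.

The event model consumes the nine per-step features in overlapping N-second
windows (N = 20 s = 40 frames at the 0.5-s hop) and emits one softmax row
per step -- each step is scored by the window that ends at it. The
sleep-wake model consumes 5-min windows of 1-Hz instantaneous heart rate
and 20-s-delayed SpO2 centred on each 30-s epoch and emits sleep/wake; an
epoch is wake when the wake output is greater than or equal to the sleep
output.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .core_io import (EVENT_ORDER, EventKind, HypnoEpoch, Recording,
                      SignalStream, SleepState)
from .features import FEATURE_NAMES, FeatureFrame, frames_to_array
from . import nn

logger = logging.getLogger("apneakit")

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EventModelConfig:
    """Hyperparameters of the LSTM event classifier."""

    n_inputs: int = 9
    n_hidden_cells: int = 80
    n_outputs: int = 4
    seq_span_s: float = 20.0       # N: seconds of context per window
    frame_step_s: float = 0.5
    epochs: int = 500
    batches_per_epoch: int = 500
    batch_size: int = 64
    learning_rate: float = 0.001
    l2_beta: float = 0.05
    grad_clip_norm: float = 5.0
    early_stop_patience: int | None = None   # epochs without loss improvement
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_inputs", "n_hidden_cells", "n_outputs", "seq_span_s",
                     "epochs", "batches_per_epoch", "batch_size",
                     "learning_rate", "l2_beta", "grad_clip_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def window_frames(self) -> int:
        return int(round(self.seq_span_s / self.frame_step_s))


@dataclass(frozen=True)
class SleepWakeConfig:
    """Hyperparameters of the sleep-wake CNN."""

    input_span_s: int = 300
    epoch_s: int = 30
    n_channels: int = 2            # IHR + delayed SpO2
    conv_blocks: int = 5
    filters: int = 10
    kernel: int = 8
    strides: tuple[int, int] = (1, 2)
    fc_nodes: tuple[int, int] = (20, 20)
    dropout_p: float = 0.5
    l2_beta: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 100
    train_steps: int = 300
    balance_classes: bool = True   # draw batches half sleep / half wake
    spo2_delay_s: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        # each conv block must halve its input length
        if sorted(self.strides) != [1, 2]:
            raise ValueError("strides must contain a 1 and a 2 per block")


@dataclass
class ProbSeries:
    """Per-step class probabilities (columns in NOR, OSA, CSA, HYP order)."""

    t_s: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(EVENT_ORDER):
            raise ValueError("probs must be (n, 4)")
        if np.any(self.probs < 0) or np.any(np.abs(self.probs.sum(1) - 1) > 1e-6):
            raise ValueError("probability rows must be nonnegative and sum to 1")

    @property
    def step_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0]) if self.t_s.size > 1 else 0.5


# ---------------------------------------------------------------------------
# R-peak detection and instantaneous heart rate


def detect_r_peaks(ecg: SignalStream) -> np.ndarray:
    """Pan-Tompkins-style QRS detection: 5-15 Hz band-pass, derivative,
    squaring, 150-ms moving integration, adaptive threshold, 0.25-s
    refractory; peak times refined on the band-passed signal."""
    fs = ecg.rate_hz
    if fs < 100:
        raise ValueError("R-peak detection needs at least 100 Hz ECG")
    if ecg.duration_s < 60:
        raise ValueError("R-peak detection needs at least 60 s of ECG")
    x = ecg.samples
    if np.ptp(x) == 0:
        logger.warning("flat ECG signal; no R peaks detected")
        return np.array([])
    sos = sps.butter(3, (5.0, 15.0), btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    feat = uniform_filter1d(np.gradient(bp) ** 2, int(round(0.150 * fs)))
    cand, props = sps.find_peaks(feat, distance=int(round(0.25 * fs)),
                                 height=1e-12 * feat.max())
    if cand.size == 0:
        logger.warning("no QRS candidates found")
        return np.array([])
    heights = props["peak_heights"]
    thr = 0.2 * np.median(heights[heights >= np.quantile(heights, 0.5)])
    keep = cand[heights > thr]
    # refine each detection to the local extremum of the band-passed ECG
    half = int(round(0.10 * fs))
    peaks = []
    for c in keep:
        sl = slice(max(c - half, 0), min(c + half + 1, x.size))
        peaks.append(sl.start + int(np.argmax(np.abs(bp[sl]))))
    peaks = np.unique(peaks)
    # enforce the refractory after refinement
    if peaks.size:
        out = [peaks[0]]
        for p in peaks[1:]:
            if (p - out[-1]) / fs >= 0.25:
                out.append(p)
        peaks = np.array(out)
    return ecg.start_s + peaks / fs


def ihr(r_peaks: np.ndarray, grid_end_s: float | None = None) -> SignalStream:
    """Instantaneous heart rate: IHR(r_i) = 60 / (r_i - r_{i-1}) bpm at each
    detected peak (from the second peak on), held to a uniform 1-Hz grid."""
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        raise ValueError("ihr needs at least two R peaks")
    rr = np.diff(r)
    if np.any(rr <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    values = 60.0 / rr                     # defined at peaks r[1:]
    end = grid_end_s if grid_end_s is not None else float(np.ceil(r[-1]))
    t = np.arange(0.0, np.floor(end) + 1.0)
    idx = np.searchsorted(r[1:], t, side="right") - 1
    held = values[np.clip(idx, 0, values.size - 1)]
    return SignalStream(held, 1.0, 0.0, "")


# ---------------------------------------------------------------------------
# Event model (LSTM)


@dataclass
class EventModel:
    cfg: EventModelConfig
    net: nn.LstmClassifier
    loss_curve: list[float] = field(default_factory=list)


def train_event_model(X: np.ndarray, y: np.ndarray,
                      cfg: EventModelConfig | None = None) -> EventModel:
    """Train the LSTM on labelled windows.

    ``X``: (n_windows, window_frames, 9); ``y``: integer class codes in
    NOR, OSA, CSA, HYP order. Deterministic for a given ``cfg.seed``.
    """
    cfg = cfg or EventModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3 or X.shape[2] != cfg.n_inputs:
        raise ValueError(f"X must be (n, frames, {cfg.n_inputs})")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(cfg.seed)
    net = nn.LstmClassifier(cfg.n_inputs, cfg.n_hidden_cells, cfg.n_outputs, rng)
    opt = nn.Adam(net.params, cfg.learning_rate)
    curve = []
    best, since_best = np.inf, 0
    for _ in range(cfg.epochs):
        losses = []
        for _ in range(cfg.batches_per_epoch):
            idx = rng.integers(0, X.shape[0], size=min(cfg.batch_size, X.shape[0]))
            loss, grads = net.loss_and_grads(X[idx], y[idx], cfg.l2_beta)
            nn.clip_grads(grads, cfg.grad_clip_norm)
            opt.step(grads)
            losses.append(loss)
        curve.append(float(np.mean(losses)))
        if cfg.early_stop_patience is not None:
            if curve[-1] < best - 1e-4:
                best, since_best = curve[-1], 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
    return EventModel(cfg, net, curve)


def _frames_matrix(frames) -> tuple[np.ndarray, np.ndarray]:
    """Accept a FeatureFrame list or a DataFrame with the canonical feature
    columns (order enforced -- permuted columns are a contract violation)."""
    if hasattr(frames, "columns"):        # pandas DataFrame
        cols = [c for c in frames.columns if c != "t_s"]
        if cols != list(FEATURE_NAMES):
            raise ValueError(
                f"feature columns {cols} do not match the expected order "
                f"{list(FEATURE_NAMES)}")
        return frames["t_s"].to_numpy(float), frames[cols].to_numpy(float)
    if frames and isinstance(frames[0], FeatureFrame):
        return frames_to_array(frames)
    raise TypeError("frames must be a FeatureFrame list or a feature DataFrame")


def predict_event_probs(model: EventModel, frames,
                        align: str = "end") -> ProbSeries:
    """One probability row per 0.5-s step.

    With ``align="end"`` each step is scored by the N-second window ending
    at it (the first window is edge-padded); with ``align="center"`` the row
    at each step comes from the window centred on it, which removes the
    half-window lag between window-majority training labels and per-step
    output (trailing steps reuse the final window).
    """
    t, X = _frames_matrix(frames)
    if X.shape[1] != model.cfg.n_inputs:
        raise ValueError(f"feature count {X.shape[1]} does not match the "
                         f"model's {model.cfg.n_inputs} inputs")
    win = model.cfg.window_frames
    if X.shape[0] < win:
        raise ValueError(f"need at least {win} frames (one full window)")
    Xp = np.vstack([np.repeat(X[:1], win - 1, axis=0), X])
    windows = np.lib.stride_tricks.sliding_window_view(
        Xp, win, axis=0).transpose(0, 2, 1)
    probs = model.net.predict_proba(np.ascontiguousarray(windows))
    if align == "center":
        idx = np.minimum(np.arange(t.size) + win // 2, t.size - 1)
        probs = probs[idx]
    elif align != "end":
        raise ValueError("align must be 'end' or 'center'")
    return ProbSeries(t, probs)


def decide_labels(probs: ProbSeries) -> np.ndarray:
    """Highest-probability class per step; exact ties resolve to the first
    class in NOR < OSA < CSA < HYP order."""
    return np.argmax(probs.probs, axis=1)


def labels_to_kinds(codes: np.ndarray) -> list[EventKind]:
    return [EVENT_ORDER[c] for c in codes]


# ---------------------------------------------------------------------------
# Sleep-wake model (CNN)


@dataclass
class SleepWakeModel:
    cfg: SleepWakeConfig
    net: nn.SleepWakeNet
    loss_curve: list[float] = field(default_factory=list)


def train_sleepwake(X: np.ndarray, y: np.ndarray,
                    cfg: SleepWakeConfig | None = None) -> SleepWakeModel:
    """Train the CNN on (n, 2, 300) windows with 0 = sleep / 1 = wake labels."""
    cfg = cfg or SleepWakeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3 or X.shape[1] != cfg.n_channels:
        raise ValueError(f"X must be (n, {cfg.n_channels}, {cfg.input_span_s})")
    if X.shape[2] < cfg.input_span_s:
        raise ValueError(f"windows of {X.shape[2]} s are shorter than the "
                         f"{cfg.input_span_s}-s input span")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(cfg.seed)
    net = nn.SleepWakeNet(cfg.n_channels, cfg.input_span_s, cfg.conv_blocks,
                          cfg.filters, cfg.kernel, cfg.strides, cfg.fc_nodes,
                          2, cfg.dropout_p, rng)
    opt = nn.Adam(net.params, cfg.learning_rate)
    by_class = [np.flatnonzero(y == c) for c in (0, 1)]
    bs = min(cfg.batch_size, X.shape[0])
    curve = []
    for _ in range(cfg.train_steps):
        if cfg.balance_classes:
            idx = np.concatenate([rng.choice(by_class[0], bs - bs // 2),
                                  rng.choice(by_class[1], bs // 2)])
        else:
            idx = rng.integers(0, X.shape[0], size=bs)
        loss, grads = net.loss_and_grads(X[idx], y[idx], cfg.l2_beta, rng)
        opt.step(grads)
        curve.append(float(loss))
    return SleepWakeModel(cfg, net, curve)


def sleepwake_windows(ihr_1hz: np.ndarray, spo2_delayed: np.ndarray,
                      n_epochs: int, cfg: SleepWakeConfig) -> np.ndarray:
    """One (2, 300) window per 30-s epoch: 5-min context centred on the
    epoch, edge-padded at the night boundaries, median-subtracted per
    window and channel."""
    span = cfg.input_span_s
    n = min(ihr_1hz.size, spo2_delayed.size)
    X = np.empty((n_epochs, 2, span))
    for e in range(n_epochs):
        centre = e * cfg.epoch_s + cfg.epoch_s // 2
        idx = np.clip(np.arange(centre - span // 2, centre + span // 2), 0, n - 1)
        X[e, 0] = ihr_1hz[idx]
        X[e, 1] = spo2_delayed[idx]
    X -= np.median(X, axis=2, keepdims=True)
    return X


def delayed_spo2(spo2: SignalStream, delay_s: int = 20) -> np.ndarray:
    """SpO2 shifted so the value at t is the saturation delay_s earlier
    (leading edge holds the first sample)."""
    d = int(round(delay_s * spo2.rate_hz))
    x = spo2.samples
    return np.concatenate([np.full(d, x[0]), x[:-d]]) if d else x.copy()


def predict_sleepwake(model: SleepWakeModel, recording: Recording
                      ) -> list[HypnoEpoch]:
    """Sleep/wake state per 30-s epoch; wake wins ties."""
    cfg = model.cfg
    r_peaks = recording.r_peaks
    if r_peaks is None:
        r_peaks = detect_r_peaks(recording.ecg)
    if r_peaks is None or len(r_peaks) < 2:
        raise ValueError("missing IHR: no usable R peaks in the recording")
    dur = recording.duration_s
    heart = ihr(r_peaks, grid_end_s=dur)
    hr = np.interp(np.arange(dur), heart.times, heart.samples)
    sp = delayed_spo2(recording.spo2, cfg.spo2_delay_s)
    n_epochs = int(dur // cfg.epoch_s)
    X = sleepwake_windows(hr, sp, n_epochs, cfg)
    probs = model.net.predict_proba(X)
    wake = probs[:, 1] >= probs[:, 0]
    return [HypnoEpoch(e * cfg.epoch_s,
                       SleepState.WAKE if wake[e] else SleepState.SLEEP)
            for e in range(n_epochs)]


# ---------------------------------------------------------------------------
# Serialization (single versioned .npz per model)


def save_model(model: EventModel | SleepWakeModel, path: str | Path) -> None:
    kind = "event" if isinstance(model, EventModel) else "sleepwake"
    meta = {"version": MODEL_FORMAT_VERSION, "kind": kind,
            "cfg": asdict(model.cfg), "loss_curve": model.loss_curve}
    np.savez(Path(path), __meta__=json.dumps(meta),
             **{k: v for k, v in model.net.params.items()})


def load_model(path: str | Path) -> EventModel | SleepWakeModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {meta['version']}")
    rng = np.random.default_rng(0)
    if meta["kind"] == "event":
        cfg = EventModelConfig(**meta["cfg"])
        net = nn.LstmClassifier(cfg.n_inputs, cfg.n_hidden_cells,
                                cfg.n_outputs, rng)
        net.params = params
        return EventModel(cfg, net, meta["loss_curve"])
    cfg_d = meta["cfg"]
    cfg_d["strides"] = tuple(cfg_d["strides"])
    cfg_d["fc_nodes"] = tuple(cfg_d["fc_nodes"])
    cfg = SleepWakeConfig(**cfg_d)
    net = nn.SleepWakeNet(cfg.n_channels, cfg.input_span_s, cfg.conv_blocks,
                          cfg.filters, cfg.kernel, cfg.strides, cfg.fc_nodes,
                          2, cfg.dropout_p, rng)
    net.params = params
    return SleepWakeModel(cfg, net, meta["loss_curve"])
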