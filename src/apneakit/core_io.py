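"""Domain types and file I/O for overnight apnea-screening recordings.

Time convention used across the package: 0-based seconds from recording
start; all intervals are half-open ``[start_s, end_s)``; the hypnogram is a
30-s grid anchored at t = 0.
"""
from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("apneakit")

MIN_EVENT_S = 10.0          #: minimum duration of a scoreable apnea/hypopnea
SPO2_VALID_RANGE = (50.0, 100.0)
HYPNO_EPOCH_S = 30.0

SIGNAL_LABELS = {
    "tho_x", "tho_y", "tho_z", "abd_x", "abd_y", "abd_z",
    "tho", "abd", "spo2", "ecg",
}


class EventKind(str, enum.Enum):
    """The four per-segment breathing classes."""

    NOR = "NOR"
    OSA = "OSA"
    CSA = "CSA"
    HYP = "HYP"


#: canonical class order (also the argmax tie-break order)
EVENT_ORDER = (EventKind.NOR, EventKind.OSA, EventKind.CSA, EventKind.HYP)

ABNORMAL_KINDS = (EventKind.OSA, EventKind.CSA, EventKind.HYP)


def parse_event_kind(text: str) -> EventKind:
    """Parse an annotation label; mixed apnea is remapped to OSA on ingest."""
    t = text.strip().upper()
    if t in ("MSA", "MIXED", "MIX"):
        return EventKind.OSA
    try:
        return EventKind(t)
    except ValueError:
        raise ValueError(f"unknown event kind {text!r}") from None


class SleepState(str, enum.Enum):
    SLEEP = "sleep"
    WAKE = "wake"


class Severity(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


SEVERITY_ORDER = (Severity.NORMAL, Severity.MILD, Severity.MODERATE, Severity.SEVERE)


@dataclass
class SignalStream:
    """A uniformly sampled 1-D signal with a recording-relative start time."""

    samples: np.ndarray
    rate_hz: float
    start_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a nonempty 1-D array")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.start_s < 0:
            raise ValueError("start_s must be nonnegative")
        if self.label and self.label not in SIGNAL_LABELS:
            raise ValueError(f"unknown signal label {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.rate_hz

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples in [t0, t1) (recording-relative seconds)."""
        i0 = int(round((t0 - self.start_s) * self.rate_hz))
        i1 = int(round((t1 - self.start_s) * self.rate_hz))
        i0 = max(i0, 0)
        return self.samples[i0:i1]


@dataclass
class TriaxialStream:
    """Three equal-length axes of one accelerometer placement."""

    x: SignalStream
    y: SignalStream
    z: SignalStream
    placement: str = "thoracic"

    def __post_init__(self) -> None:
        if self.placement not in ("thoracic", "abdominal"):
            raise ValueError("placement must be 'thoracic' or 'abdominal'")
        a, b, c = self.x, self.y, self.z
        if not (a.rate_hz == b.rate_hz == c.rate_hz):
            raise ValueError("triaxial axes must share rate_hz")
        if not (a.start_s == b.start_s == c.start_s):
            raise ValueError("triaxial axes must share start_s")
        if not (len(a) == len(b) == len(c)):
            raise ValueError("triaxial axes must share length")

    @property
    def rate_hz(self) -> float:
        return self.x.rate_hz

    @property
    def start_s(self) -> float:
        return self.x.start_s

    @property
    def duration_s(self) -> float:
        return self.x.duration_s

    def as_matrix(self) -> np.ndarray:
        """(n, 3) array of the x/y/z samples."""
        return np.stack([self.x.samples, self.y.samples, self.z.samples], axis=1)


@dataclass(frozen=True)
class EventInterval:
    """A typed breathing-event span, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    kind: EventKind

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.kind in ABNORMAL_KINDS and self.duration_s < MIN_EVENT_S - 1e-9:
            raise ValueError(
                f"{self.kind.value} event of {self.duration_s:.1f} s is shorter "
                f"than the {MIN_EVENT_S:.0f}-s minimum"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class HypnoEpoch:
    """One 30-s sleep/wake epoch starting at a multiple of 30 s."""

    start_s: float
    state: SleepState

    def __post_init__(self) -> None:
        if abs(self.start_s % HYPNO_EPOCH_S) > 1e-9:
            raise ValueError("hypnogram epochs must start on the 30-s grid")
        if not isinstance(self.state, SleepState):
            object.__setattr__(self, "state", SleepState(str(self.state)))


def validate_hypnogram(epochs: Sequence[HypnoEpoch]) -> None:
    """Epochs must tile the recording contiguously without overlap."""
    starts = [e.start_s for e in epochs]
    expect = [starts[0] + i * HYPNO_EPOCH_S for i in range(len(starts))]
    if not np.allclose(starts, expect):
        raise ValueError("hypnogram epochs must tile contiguously on the 30-s grid")


@dataclass
class Recording:
    """Bundle of the raw streams plus optional expert annotations."""

    tho_taa: TriaxialStream
    abd_taa: TriaxialStream
    spo2: SignalStream
    ecg: SignalStream | None = None
    r_peaks: np.ndarray | None = None
    events: list[EventInterval] | None = None
    hypnogram: list[HypnoEpoch] | None = None

    def __post_init__(self) -> None:
        if self.ecg is None and self.r_peaks is None:
            raise ValueError("recording needs an ECG stream or an R-peak list")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=float)
            if self.r_peaks.size >= 2 and not np.all(np.diff(self.r_peaks) > 0):
                raise ValueError("r_peaks must be strictly increasing")
        streams = [self.tho_taa.x, self.abd_taa.x, self.spo2]
        if self.ecg is not None:
            streams.append(self.ecg)
        t0 = max(s.start_s for s in streams)
        t1 = min(s.end_s for s in streams)
        if not t1 > t0:
            raise ValueError("signal streams do not overlap in time")
        if self.hypnogram:
            validate_hypnogram(self.hypnogram)

    @property
    def duration_s(self) -> float:
        return min(self.tho_taa.duration_s, self.abd_taa.duration_s)


@dataclass
class AhiReport:
    """Apnea–hypopnea index summary for one scored night."""

    ahi: float
    severity: Severity
    counts: dict[EventKind, int]
    tst_h: float
    events: list[EventInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k in ABNORMAL_KINDS:
            self.counts.setdefault(k, 0)
        if self.tst_h > 0:
            n = sum(self.counts[k] for k in ABNORMAL_KINDS)
            if abs(self.ahi - n / self.tst_h) > 1e-6 * max(1.0, self.ahi):
                raise ValueError("ahi inconsistent with counts / tst_h")


# ---------------------------------------------------------------------------
# SpO2 cleaning


def clean_spo2(samples: np.ndarray) -> np.ndarray:
    """Replace dropouts/garbage (non-finite or outside 50–100 %) by linear
    interpolation between valid neighbours; edges hold the nearest valid value.
    """
    x = np.asarray(samples, dtype=float).copy()
    lo, hi = SPO2_VALID_RANGE
    good = np.isfinite(x) & (x >= lo) & (x <= hi)
    if not good.any():
        raise ValueError("SpO2 trace contains no valid samples in [50, 100]")
    if not good.all():
        idx = np.arange(x.size)
        x[~good] = np.interp(idx[~good], idx[good], x[good])
    return x


# ---------------------------------------------------------------------------
# CSV I/O (one file per rate group)

_CSV_FILES = {
    "taa": "taa.csv",
    "spo2": "spo2.csv",
    "ecg": "ecg.csv",
    "r_peaks": "r_peaks.csv",
    "events": "events.csv",
    "hypnogram": "hypnogram.csv",
    "manifest": "recording.json",
}

_TAA_COLS = ["tho_x", "tho_y", "tho_z", "abd_x", "abd_y", "abd_z"]


def write_recording(rec: Recording, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write a recording as CSV files (or EDF + annotation CSVs) in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        taa = np.hstack([rec.tho_taa.as_matrix(), rec.abd_taa.as_matrix()])
        pd.DataFrame(taa, columns=_TAA_COLS).to_csv(out / _CSV_FILES["taa"],
                                                    index=False, float_format="%.10g")
        pd.DataFrame({"spo2": rec.spo2.samples}).to_csv(
            out / _CSV_FILES["spo2"], index=False, float_format="%.10g")
        if rec.ecg is not None:
            pd.DataFrame({"ecg": rec.ecg.samples}).to_csv(
                out / _CSV_FILES["ecg"], index=False, float_format="%.10g")
    elif fmt == "edf":
        streams = [rec.tho_taa.x, rec.tho_taa.y, rec.tho_taa.z,
                   rec.abd_taa.x, rec.abd_taa.y, rec.abd_taa.z, rec.spo2]
        if rec.ecg is not None:
            streams.append(rec.ecg)
        write_edf(streams, out / "recording.edf")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    manifest = {
        "format": fmt,
        "taa_rate_hz": rec.tho_taa.rate_hz,
        "spo2_rate_hz": rec.spo2.rate_hz,
        "ecg_rate_hz": rec.ecg.rate_hz if rec.ecg is not None else None,
        "start_s": rec.tho_taa.start_s,
    }
    (out / _CSV_FILES["manifest"]).write_text(json.dumps(manifest, indent=1))
    if rec.r_peaks is not None:
        pd.DataFrame({"r_peak_s": rec.r_peaks}).to_csv(
            out / _CSV_FILES["r_peaks"], index=False, float_format="%.12g")
    if rec.events is not None:
        write_events(rec.events, out / _CSV_FILES["events"])
    if rec.hypnogram is not None:
        write_hypnogram(rec.hypnogram, out / _CSV_FILES["hypnogram"])
    return out


def read_recording(path: str | Path, fmt: str | None = None,
                   taa_rate_hz: float = 50.0, spo2_rate_hz: float = 1.0,
                   ecg_rate_hz: float = 500.0) -> Recording:
    """Read a recording directory written by :func:`write_recording`.

    SpO2 cleaning (interpolation across dropouts / out-of-range values) is
    applied here, once, at read time.
    """
    p = Path(path)
    if not p.is_dir():
        raise FileNotFoundError(f"recording directory not found: {p}")
    man = p / _CSV_FILES["manifest"]
    start_s = 0.0
    if man.exists():
        m = json.loads(man.read_text())
        fmt = fmt or m.get("format", "csv")
        taa_rate_hz = m.get("taa_rate_hz", taa_rate_hz)
        spo2_rate_hz = m.get("spo2_rate_hz", spo2_rate_hz)
        ecg_rate_hz = m.get("ecg_rate_hz") or ecg_rate_hz
        start_s = m.get("start_s", 0.0)
    fmt = fmt or "csv"

    ecg = None
    if fmt == "csv":
        taa_path = p / _CSV_FILES["taa"]
        if not taa_path.exists():
            raise FileNotFoundError(
                f"missing mandatory channel group 'taa' (expected {taa_path})")
        try:
            taa = pd.read_csv(taa_path)
        except Exception as exc:  # pragma: no cover - pandas gives context
            raise ValueError(f"unparseable TAA file {taa_path}: {exc}") from exc
        missing = [c for c in _TAA_COLS if c not in taa.columns]
        if missing:
            raise ValueError(f"TAA file lacks channel columns {missing}")
        spo2_path = p / _CSV_FILES["spo2"]
        if not spo2_path.exists():
            raise FileNotFoundError(
                f"missing mandatory channel 'spo2' (expected {spo2_path})")
        spo2_raw = pd.read_csv(spo2_path)["spo2"].to_numpy(float)

        def s(col: str) -> SignalStream:
            return SignalStream(taa[col].to_numpy(float), taa_rate_hz, start_s, col)

        tho = TriaxialStream(s("tho_x"), s("tho_y"), s("tho_z"), "thoracic")
        abd = TriaxialStream(s("abd_x"), s("abd_y"), s("abd_z"), "abdominal")
        ecg_path = p / _CSV_FILES["ecg"]
        if ecg_path.exists():
            ecg = SignalStream(pd.read_csv(ecg_path)["ecg"].to_numpy(float),
                               ecg_rate_hz, start_s, "ecg")
    elif fmt == "edf":
        streams = {st.label: st for st in read_edf(p / "recording.edf")}
        for role in _TAA_COLS + ["spo2"]:
            if role not in streams:
                raise FileNotFoundError(f"missing mandatory channel '{role}' in EDF")
        tho = TriaxialStream(streams["tho_x"], streams["tho_y"], streams["tho_z"],
                             "thoracic")
        abd = TriaxialStream(streams["abd_x"], streams["abd_y"], streams["abd_z"],
                             "abdominal")
        spo2_raw = streams["spo2"].samples
        spo2_rate_hz = streams["spo2"].rate_hz
        ecg = streams.get("ecg")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    spo2 = SignalStream(clean_spo2(spo2_raw), spo2_rate_hz, start_s, "spo2")
    r_peaks = None
    rp = p / _CSV_FILES["r_peaks"]
    if rp.exists():
        r_peaks = pd.read_csv(rp)["r_peak_s"].to_numpy(float)
    events = None
    for name in (_CSV_FILES["events"], "truth_" + _CSV_FILES["events"]):
        if (p / name).exists():
            events = read_events(p / name)
            break
    hypno = None
    for name in (_CSV_FILES["hypnogram"], "truth_" + _CSV_FILES["hypnogram"]):
        if (p / name).exists():
            hypno = read_hypnogram(p / name)
            break
    return Recording(tho, abd, spo2, ecg, r_peaks, events, hypno)


def write_events(events: Iterable[EventInterval], path: str | Path) -> None:
    rows = [(e.start_s, e.end_s, e.kind.value) for e in events]
    pd.DataFrame(rows, columns=["start_s", "end_s", "kind"]).to_csv(
        Path(path), index=False, float_format="%.12g")


def read_events(path: str | Path) -> list[EventInterval]:
    df = pd.read_csv(Path(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(EventInterval(float(row["start_s"]), float(row["end_s"]),
                                     parse_event_kind(str(row["kind"]))))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: bad annotation at record {i}: {exc}") from exc
    return out


def write_hypnogram(epochs: Iterable[HypnoEpoch], path: str | Path) -> None:
    rows = [(e.start_s, e.state.value) for e in epochs]
    pd.DataFrame(rows, columns=["start_s", "state"]).to_csv(
        Path(path), index=False, float_format="%.12g")


def read_hypnogram(path: str | Path) -> list[HypnoEpoch]:
    df = pd.read_csv(Path(path))
    return [HypnoEpoch(float(r["start_s"]), SleepState(str(r["state"]).strip()))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# AHI report JSON


def write_report(report: AhiReport, path: str | Path) -> None:
    doc = {
        "ahi": report.ahi,
        "severity": report.severity.value,
        "counts": {k.value: int(v) for k, v in report.counts.items()},
        "tst_h": report.tst_h,
        "events": [
            {"start_s": e.start_s, "end_s": e.end_s, "kind": e.kind.value}
            for e in report.events
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report(path: str | Path) -> AhiReport:
    doc = json.loads(Path(path).read_text())
    return AhiReport(
        ahi=float(doc["ahi"]),
        severity=Severity(doc["severity"]),
        counts={EventKind(k): int(v) for k, v in doc["counts"].items()},
        tst_h=float(doc["tst_h"]),
        events=[EventInterval(d["start_s"], d["end_s"], EventKind(d["kind"]))
                for d in doc["events"]],
    )


# ---------------------------------------------------------------------------
# Minimal EDF codec (16-bit, one-second data records, per-signal sample counts)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(streams: Sequence[SignalStream], path: str | Path) -> None:
    """Write signals to a plain EDF file with 1-s data records.

    Signals are linearly quantized to the 16-bit digital range; all stream
    durations must be whole seconds and equal.
    """
    durs = {round(s.duration_s, 9) for s in streams}
    if len(durs) != 1:
        raise ValueError("EDF export requires equal stream durations")
    dur = durs.pop()
    if abs(dur - round(dur)) > 1e-9:
        raise ValueError("EDF export requires whole-second durations")
    n_rec = int(round(dur))
    ns = len(streams)
    phys = []
    for s in streams:
        lo, hi = float(np.min(s.samples)), float(np.max(s.samples))
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("apneakit", 80))
        fh.write(_pad("synthetic recording", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (1 + ns)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for s in streams:
            fh.write(_pad(s.label or "sig", 16))
        for _ in streams:
            fh.write(_pad("", 80))
        for _ in streams:
            fh.write(_pad("au", 8))
        for lo, hi in phys:
            fh.write(_pad(f"{lo:.6g}"[:8], 8))
        for lo, hi in phys:
            fh.write(_pad(f"{hi:.6g}"[:8], 8))
        for _ in streams:
            fh.write(_pad("-32768", 8))
        for _ in streams:
            fh.write(_pad("32767", 8))
        for _ in streams:
            fh.write(_pad("", 80))
        for s in streams:
            spr = s.rate_hz
            if abs(spr - round(spr)) > 1e-9:
                raise ValueError("EDF export requires integer samples per second")
            fh.write(_pad(str(int(round(spr))), 8))
        for _ in streams:
            fh.write(_pad("", 32))
        # digital conversion
        digs = []
        for s, (lo, hi) in zip(streams, phys):
            # re-read the physical bounds exactly as the 8-char header stores them
            lo8 = float(f"{lo:.6g}"[:8])
            hi8 = float(f"{hi:.6g}"[:8])
            gain = 65535.0 / (hi8 - lo8)
            d = np.round((s.samples - lo8) * gain - 32768.0)
            digs.append(np.clip(d, -32768, 32767).astype("<i2"))
        for r in range(n_rec):
            for s, d in zip(streams, digs):
                spr = int(round(s.rate_hz))
                fh.write(d[r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> list[SignalStream]:
    """Read an EDF file written by :func:`write_edf` (or any 16-bit EDF with
    one-second records)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def f(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", "replace").strip()

    n_rec = int(f(236, 8))
    rec_dur = float(f(244, 8))
    ns = int(f(252, 4))
    h = 256
    labels = [f(h + 16 * i, 16) for i in range(ns)]
    h += 16 * ns + 80 * ns + 8 * ns
    pmin = [float(f(h + 8 * i, 8)) for i in range(ns)]
    h += 8 * ns
    pmax = [float(f(h + 8 * i, 8)) for i in range(ns)]
    h += 8 * ns
    dmin = [float(f(h + 8 * i, 8)) for i in range(ns)]
    h += 8 * ns
    dmax = [float(f(h + 8 * i, 8)) for i in range(ns)]
    h += 8 * ns + 80 * ns
    spr = [int(f(h + 8 * i, 8)) for i in range(ns)]
    h = 256 * (1 + ns)
    rec_len = sum(spr)
    data = np.frombuffer(raw[h:h + 2 * rec_len * n_rec], dtype="<i2")
    if data.size < rec_len * n_rec:
        raise ValueError(f"{path}: EDF data section truncated "
                         f"(expected {rec_len * n_rec} samples, got {data.size})")
    data = data.reshape(n_rec, rec_len)
    out = []
    col = 0
    for i in range(ns):
        dig = data[:, col:col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        label = labels[i].lower()
        out.append(SignalStream(pmin[i] + (dig - dmin[i]) * gain,
                                spr[i] / rec_dur, 0.0,
                                label if label in SIGNAL_LABELS else ""))
    return out
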