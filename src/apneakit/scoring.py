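"""Desaturation detection, label fusion, event extraction, AHI and metrics.

The scoring chain after the classifiers:

1. mark every >=3 % SpO2 desaturation (first difference accumulated by a
   20-s unity-window convolution, marks shifted 20 s earlier to compensate
   the physiological delay);
2. fuse: steps classified NOR under an active desaturation mark become HYP;
   any abnormal label inside a wake epoch is reset to NOR;
3. extract events: maximal same-kind runs, same-kind runs separated by
   under 2 s of NOR merged, abnormal runs shorter than 10 s dropped;
4. AHI = abnormal events per hour of sleep, graded normal / mild /
   moderate / severe at the standard 5 / 15 / 30 cutoffs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (ABNORMAL_KINDS, EVENT_ORDER, AhiReport, EventInterval,
                      EventKind, HypnoEpoch, MIN_EVENT_S, Severity,
                      SignalStream, SleepState)
from .models import ProbSeries, decide_labels

DESAT_DROP_PCT = 3.0
DESAT_ACCUM_S = 20
DESAT_SHIFT_S = 20
EVENT_MERGE_GAP_S = 2.0

_NOR = EVENT_ORDER.index(EventKind.NOR)
_HYP = EVENT_ORDER.index(EventKind.HYP)


@dataclass
class DesatMark:
    """Per-second desaturation marks on the SpO2 clock (after the 20-s
    forward shift) with the maximum accumulated drop of each marked run."""

    marks: np.ndarray                       # bool, one per SpO2 second
    depths: np.ndarray                      # % drop, 0 where unmarked
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.marks = np.asarray(self.marks, dtype=bool)
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths[self.marks] < DESAT_DROP_PCT):
            raise ValueError("marks exist where the accumulated drop is < 3 %")

    @property
    def n_runs(self) -> int:
        m = self.marks.astype(int)
        return int(np.sum(np.diff(np.concatenate([[0], m])) == 1))


def detect_desaturation(spo2: SignalStream) -> DesatMark:
    """Mark every SpO2 desaturation whose 20-s accumulated drop reaches 3 %.

    The first difference of the 1-Hz trace is convolved with a 20-sample
    all-ones kernel; sample k of the result is the total drop over the 20 s
    ending at k. Samples at or past 3 % are marked and the mark series is
    shifted 20 s earlier in time.
    """
    if spo2.rate_hz != 1.0:
        raise ValueError("desaturation detection expects a 1-Hz SpO2 trace")
    if spo2.duration_s < 60:
        raise ValueError("desaturation detection needs at least 60 s of SpO2")
    x = spo2.samples
    n = x.size
    d = np.diff(x)
    acc = np.convolve(d, np.ones(DESAT_ACCUM_S))[:d.size]
    # acc[j] = sum(d[j-19 .. j]) = x[j+1] - x[max(j-19, 0)]; time of sample
    # j of acc is j+1 s. Mark where the accumulated *drop* reaches 3 %.
    drop = -acc
    marked_t = np.flatnonzero(drop >= DESAT_DROP_PCT) + 1
    marks = np.zeros(n, dtype=bool)
    depths = np.zeros(n)
    shifted = marked_t - DESAT_SHIFT_S
    keep = shifted >= 0
    marks[shifted[keep]] = True
    depths[shifted[keep]] = drop[marked_t[keep] - 1]
    # each contiguous run carries its maximum drop depth
    if marks.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], marks.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            depths[s:e] = depths[s:e].max()
    return DesatMark(marks, depths, spo2.start_s)


def hypno_state_at(hypno: list[HypnoEpoch], t: np.ndarray) -> np.ndarray:
    """Sleep(0)/wake(1) state of the epoch containing each time (clamped to
    the hypnogram's span)."""
    starts = np.array([e.start_s for e in hypno])
    states = np.array([e.state == SleepState.WAKE for e in hypno])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(hypno) - 1)
    return states[idx]


def fuse(probs: ProbSeries, desat: DesatMark | None,
         hypno: list[HypnoEpoch] | None) -> np.ndarray:
    """Combine classifier output with desaturation marks and the hypnogram.

    A step whose argmax is NOR under an active desaturation mark becomes
    HYP; classifier output is kept for non-NOR argmax. The rescue acts per
    desaturation run: a marked run that already overlaps abnormal argmax
    labels belongs to a detected event, so it does not spawn an extra HYP
    span (the rule exists to catch hypopneas the classifier missed).
    Every abnormal label inside a wake epoch is reset to NOR.
    """
    labels = decide_labels(probs)
    t = probs.t_s
    if desat is not None:
        if desat.start_s > t[0]:
            raise ValueError("desaturation marks start after the probability "
                             "series; streams are misaligned")
        sec = np.floor(t - desat.start_s).astype(int)
        in_range = sec < desat.marks.size
        active = np.zeros(t.size, dtype=bool)
        active[in_range] = desat.marks[sec[in_range]]
        # split the active steps into contiguous runs
        edges = np.flatnonzero(np.diff(np.concatenate(
            [[0], active.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            if not np.any(labels[s:e] != _NOR):
                labels[s:e] = _HYP
    if hypno is not None and len(hypno) > 0:
        wake = hypno_state_at(hypno, t)
        labels = np.where(wake, _NOR, labels)
    return labels


def extract_events(step_labels: np.ndarray, step_s: float = 0.5,
                   t0: float = 0.0) -> list[EventInterval]:
    """Abnormal events from per-step labels: same-kind runs separated by
    under 2 s of NOR are merged, then runs shorter than 10 s are dropped."""
    labels = np.asarray(step_labels, dtype=int)
    n = labels.size
    runs = []                              # (start_idx, end_idx_excl, code)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append([i, j, labels[i]])
        i = j
    # merge same-kind abnormal runs across short NOR gaps
    merged = []
    for run in runs:
        if (len(merged) >= 2 and run[2] == merged[-2][2] and run[2] != _NOR
                and merged[-1][2] == _NOR
                and (merged[-1][1] - merged[-1][0]) * step_s < EVENT_MERGE_GAP_S):
            merged[-2][1] = run[1]
            merged.pop()
        elif merged and run[2] == merged[-1][2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    events = []
    for s, e, code in merged:
        if code == _NOR:
            continue
        dur = (e - s) * step_s
        if dur >= MIN_EVENT_S:
            events.append(EventInterval(t0 + s * step_s, t0 + e * step_s,
                                        EVENT_ORDER[code]))
    return events


def compute_ahi(events: list[EventInterval],
                hypno: list[HypnoEpoch]) -> AhiReport:
    """AHI = (#OSA + #CSA + #HYP) / hours of sleep, with severity grade."""
    if not hypno:
        raise ValueError("compute_ahi needs a nonempty hypnogram")
    n_sleep = sum(1 for e in hypno if e.state == SleepState.SLEEP)
    tst_h = n_sleep * 30.0 / 3600.0
    if tst_h == 0:
        raise ValueError("no sleep scored; AHI undefined")
    counts = {k: 0 for k in ABNORMAL_KINDS}
    for ev in events:
        if ev.kind in counts:
            counts[ev.kind] += 1
    ahi = sum(counts.values()) / tst_h
    return AhiReport(ahi=ahi, severity=severity_grade(ahi), counts=counts,
                     tst_h=tst_h, events=sorted(events, key=lambda e: e.start_s))


def severity_grade(ahi: float) -> Severity:
    """Standard AHI severity bins; boundary values go to the upper bin."""
    if ahi < 0:
        raise ValueError("ahi must be nonnegative")
    if ahi < 5:
        return Severity.NORMAL
    if ahi < 15:
        return Severity.MILD
    if ahi < 30:
        return Severity.MODERATE
    return Severity.SEVERE


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = predicted, columns = expert label."""

    counts: np.ndarray
    classes: list[str] = field(default_factory=lambda: [k.value for k in EVENT_ORDER])

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts.ndim != 2
                or self.counts.shape[0] != self.counts.shape[1]
                or self.counts.shape[0] != len(self.classes)):
            raise ValueError("counts must be square and match the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, predicted: np.ndarray, truth: np.ndarray,
                    n_classes: int = 4, classes: list[str] | None = None):
        counts = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(counts, (np.asarray(predicted, int), np.asarray(truth, int)), 1)
        return cls(counts, classes or [k.value for k in EVENT_ORDER[:n_classes]])

    def __str__(self) -> str:
        w = max(len(c) for c in self.classes) + 2
        head = " " * w + "".join(f"{c:>{w}}" for c in self.classes)
        rows = [head] + [
            f"{c:>{w}}" + "".join(f"{v:>{w}d}" for v in row)
            for c, row in zip(self.classes, self.counts)
        ]
        return "\n".join(rows)


def confusion_accuracy(m: ConfusionMatrix) -> float:
    """100 x trace / total, in percent."""
    total = m.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(m.counts)) / float(total)


@dataclass
class MetricsBundle:
    confusion: ConfusionMatrix
    precision: float
    sensitivity: float
    f1: float
    accuracy_pct: float
    ahi_difference: float | None = None


def rasterize_events(events: list[EventInterval], t: np.ndarray) -> np.ndarray:
    """Per-step class codes from an event list (NOR where no event covers t)."""
    out = np.full(t.size, _NOR, dtype=int)
    for ev in events:
        out[(t >= ev.start_s) & (t < ev.end_s)] = EVENT_ORDER.index(ev.kind)
    return out


def evaluate(predicted, truth, grid_s: float = 0.5,
             duration_s: float | None = None,
             pred_ahi: float | None = None,
             truth_ahi: float | None = None) -> MetricsBundle:
    """Per-step four-class confusion matrix plus binary abnormal-vs-NOR
    precision / sensitivity / F1 (F1 = 2PS/(P+S)); optionally |AHI_pred -
    AHI_truth| when both AHI values are given.

    ``predicted`` and ``truth`` may each be label arrays on the common grid
    or event lists (rasterized onto the grid; ``duration_s`` required then).
    """

    def to_labels(obj):
        if isinstance(obj, (list, tuple)) and (not obj or
                                               isinstance(obj[0], EventInterval)):
            if duration_s is None:
                raise ValueError("duration_s required to rasterize event lists")
            t = np.arange(0.0, duration_s, grid_s)
            return rasterize_events(list(obj), t)
        return np.asarray(obj, dtype=int)

    p = to_labels(predicted)
    g = to_labels(truth)
    if g.size == 0:
        raise ValueError("empty truth labels")
    if p.size != g.size:
        raise ValueError(f"prediction ({p.size}) and truth ({g.size}) grids differ")
    cm = ConfusionMatrix.from_labels(p, g)
    pa = p != _NOR
    ga = g != _NOR
    tp = int(np.sum(pa & ga))
    fp = int(np.sum(pa & ~ga))
    fn = int(np.sum(~pa & ga))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    ahi_diff = (abs(pred_ahi - truth_ahi)
                if pred_ahi is not None and truth_ahi is not None else None)
    return MetricsBundle(cm, precision, sensitivity, f1,
                         confusion_accuracy(cm), ahi_diff)


def macro_f1(predicted: np.ndarray, truth: np.ndarray,
             n_classes: int = 4) -> float:
    """Unweighted mean of per-class F1 over the classes present in truth."""
    p = np.asarray(predicted, int)
    g = np.asarray(truth, int)
    scores = []
    for c in range(n_classes):
        tp = np.sum((p == c) & (g == c))
        fp = np.sum((p == c) & (g != c))
        fn = np.sum((p != c) & (g == c))
        if tp + fn == 0:
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn)
        scores.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(scores)) if scores else 0.0
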