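"""Desaturation detection, fusion rules, event extraction, AHI, metrics."""
import numpy as np
import pytest

from apneakit.core_io import (EVENT_ORDER, EventInterval, EventKind,
                              HypnoEpoch, Severity, SignalStream, SleepState)
from apneakit.models import ProbSeries
from apneakit.scoring import (ConfusionMatrix, compute_ahi,
                              confusion_accuracy, detect_desaturation,
                              evaluate, extract_events, fuse, macro_f1,
                              severity_grade)

NOR, OSA, CSA, HYP = range(4)


def brute_force_desat(x):
    """Oracle: explicit loop over the difference sequence."""
    n = x.size
    marks = np.zeros(n, dtype=bool)
    for t in range(1, n):
        drop = x[max(t - 20, 0)] - x[t]
        if drop >= 3.0 and t - 20 >= 0:
            marks[t - 20] = True
    return marks


def spo2(x):
    return SignalStream(np.asarray(x, float), 1.0, 0.0, "spo2")


class TestDesaturation:
    def test_constant_trace_unmarked(self):
        assert detect_desaturation(spo2(np.full(300, 97.0))).n_runs == 0

    def test_four_pct_ramp_marked_once_at_shifted_onset(self):
        """The 3 % threshold is crossed 7.5 s into a 4 %-per-10-s ramp, so
        after the 20-s compensation the run starts at (100 + 7.5) - 20."""
        x = np.full(300, 97.0)
        x[100:110] = 97.0 - 0.4 * np.arange(1, 11)
        x[110:] = 93.0
        mark = detect_desaturation(spo2(x))
        assert mark.n_runs == 1
        onset = np.flatnonzero(mark.marks)[0]
        oracle_onset = np.flatnonzero(brute_force_desat(x))[0]
        assert onset == oracle_onset
        assert abs(onset - (107.5 - 20)) <= 1
        assert mark.depths[mark.marks].max() >= 4.0

    def test_two_pct_dip_unmarked(self):
        x = np.full(300, 97.0)
        x[100:110] = 97.0 - 0.2 * np.arange(1, 11)
        x[110:130] = 95.0
        x[130:] = 97.0
        assert detect_desaturation(spo2(x)).n_runs == 0

    def test_matches_brute_force_on_random_traces(self):
        g = np.random.default_rng(2024)
        for _ in range(200):
            x = np.clip(97.0 + np.cumsum(g.normal(0, 0.35, 240)), 80.0, 100.0)
            got = detect_desaturation(spo2(x)).marks
            np.testing.assert_array_equal(got, brute_force_desat(x))


def probs_from_labels(codes, t0=0.0):
    p = np.full((len(codes), 4), 0.1)
    p[np.arange(len(codes)), codes] = 0.7
    return ProbSeries(t0 + 0.5 * np.arange(len(codes)), p)


def sleep_hypno(n, wake_from=None, wake_to=None):
    out = []
    for i in range(n):
        state = SleepState.SLEEP
        if wake_from is not None and wake_from <= 30 * i < wake_to:
            state = SleepState.WAKE
        out.append(HypnoEpoch(30.0 * i, state))
    return out


class TestFuse:
    def desat(self, n, active):
        marks = np.zeros(n, dtype=bool)
        marks[active] = True
        depths = np.where(marks, 4.0, 0.0)
        from apneakit.scoring import DesatMark

        return DesatMark(marks, depths)

    def test_nor_with_desat_becomes_hyp(self):
        probs = probs_from_labels([NOR] * 40)
        fused = fuse(probs, self.desat(40, slice(5, 15)), sleep_hypno(1))
        assert set(fused[10:30]) == {HYP}
        assert set(fused[32:]) == {NOR}

    def test_osa_with_desat_kept(self):
        probs = probs_from_labels([OSA] * 40)
        fused = fuse(probs, self.desat(40, slice(0, 20)), sleep_hypno(1))
        assert set(fused) == {OSA}

    def test_abnormal_in_wake_reset_to_nor(self):
        probs = probs_from_labels([OSA] * 120)
        fused = fuse(probs, None, sleep_hypno(2, wake_from=0, wake_to=30))
        assert set(fused[:60]) == {NOR}
        assert set(fused[60:]) == {OSA}

    def test_misalignment_rejected(self):
        from apneakit.scoring import DesatMark

        probs = probs_from_labels([NOR] * 40)
        late = DesatMark(np.zeros(40, bool), np.zeros(40), start_s=30.0)
        with pytest.raises(ValueError, match="misaligned"):
            fuse(probs, late, sleep_hypno(1))


class TestExtractEvents:
    def test_long_run_becomes_event(self):
        ev = extract_events(np.array([OSA] * 30))
        assert len(ev) == 1
        assert ev[0].kind is EventKind.OSA
        assert ev[0].duration_s == 15.0

    def test_short_isolated_run_dropped(self):
        labels = np.array([NOR] * 10 + [OSA] * 12 + [NOR] * 10)
        assert extract_events(labels) == []

    def test_merge_across_short_nor_gap(self):
        labels = np.array([OSA] * 20 + [NOR] * 2 + [OSA] * 20)
        ev = extract_events(labels)
        assert len(ev) == 1
        assert ev[0].duration_s == 21.0

    def test_no_merge_across_long_gap_or_kinds(self):
        labels = np.array([OSA] * 24 + [NOR] * 8 + [OSA] * 24)
        assert len(extract_events(labels)) == 2
        labels = np.array([OSA] * 20 + [NOR] * 2 + [CSA] * 24)
        kinds = [e.kind for e in extract_events(labels)]
        assert kinds == [EventKind.OSA, EventKind.CSA]

    def test_events_never_overlap(self, rng):
        labels = rng.integers(0, 4, 2000)
        events = sorted(extract_events(labels), key=lambda e: e.start_s)
        for a, b in zip(events, events[1:]):
            assert a.end_s <= b.start_s
        assert all(e.duration_s >= 10.0 for e in events)


class TestAhi:
    def test_thirty_events_six_hours(self):
        events = [EventInterval(120.0 * i, 120.0 * i + 15, EventKind.OSA)
                  for i in range(30)]
        rep = compute_ahi(events, sleep_hypno(720))
        assert rep.ahi == pytest.approx(5.0)
        assert rep.tst_h == pytest.approx(6.0)
        assert rep.severity is Severity.MILD

    def test_zero_events_normal(self):
        rep = compute_ahi([], sleep_hypno(720))
        assert rep.ahi == 0.0 and rep.severity is Severity.NORMAL

    def test_event_order_invariance(self, rng):
        events = [EventInterval(60.0 * i, 60.0 * i + 12, EventKind.HYP)
                  for i in range(10)]
        shuffled = list(events)
        rng.shuffle(shuffled)
        a = compute_ahi(events, sleep_hypno(120))
        b = compute_ahi(shuffled, sleep_hypno(120))
        assert a.ahi == b.ahi and a.events == b.events

    def test_all_wake_rejected(self):
        with pytest.raises(ValueError, match="no sleep"):
            compute_ahi([], sleep_hypno(4, wake_from=0, wake_to=120))


class TestSeverity:
    @pytest.mark.parametrize("ahi,grade", [
        (1.8, Severity.NORMAL),       # normal-group mean
        (4.99, Severity.NORMAL),
        (5.0, Severity.MILD),
        (9.4, Severity.MILD),
        (15.0, Severity.MODERATE),    # boundary goes to the upper bin
        (21.7, Severity.MODERATE),
        (30.0, Severity.SEVERE),
        (61.1, Severity.SEVERE),      # severe-group mean
    ])
    def test_cutoffs(self, ahi, grade):
        assert severity_grade(ahi) is grade

    def test_monotone_in_ahi(self):
        from apneakit.core_io import SEVERITY_ORDER

        grades = [SEVERITY_ORDER.index(severity_grade(a))
                  for a in np.linspace(0, 80, 400)]
        assert np.all(np.diff(grades) >= 0)


TABLE6 = np.array([[3, 0, 0, 0],
                   [0, 8, 3, 0],
                   [0, 0, 11, 3],
                   [0, 0, 0, 28]])

TABLE7 = np.array([[37788, 232, 470, 1824],
                   [1391, 7485, 2132, 1213],
                   [21, 35, 1855, 32],
                   [556, 1703, 149, 2138]])


class TestMetrics:
    def test_perfect_prediction(self):
        labels = np.array([NOR] * 50 + [OSA] * 30)
        m = evaluate(labels, labels, pred_ahi=12.0, truth_ahi=12.0)
        assert m.precision == m.sensitivity == m.f1 == 1.0
        assert m.ahi_difference == 0.0

    def test_f1_formula_at_half(self):
        truth = np.array([OSA] * 2 + [NOR] * 2)
        pred = np.array([OSA, NOR, OSA, NOR])
        m = evaluate(pred, truth)
        assert m.precision == 0.5 and m.sensitivity == 0.5
        assert m.f1 == pytest.approx(0.5)

    def test_event_list_rasterization(self):
        truth = [EventInterval(10.0, 25.0, EventKind.CSA)]
        m = evaluate(truth, truth, duration_s=60.0)
        assert m.f1 == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            evaluate(np.array([0, 1]), np.array([], dtype=int))

    def test_printed_osa_row_precision(self):
        cm = ConfusionMatrix(TABLE7)
        osa_row = cm.counts[1]
        assert osa_row.sum() == 12221
        assert osa_row[1] / osa_row.sum() == pytest.approx(0.612, abs=5e-4)

    def test_confusion_accuracy_identity(self):
        assert confusion_accuracy(ConfusionMatrix(np.eye(4, dtype=int) * 7)) == 100.0

    def test_severity_table_accuracy(self):
        cls = ["Normal", "Mild", "Moderate", "Severe"]
        acc = confusion_accuracy(ConfusionMatrix(TABLE6, cls))
        assert acc == pytest.approx(100 * 50 / 56)
        assert round(acc, 1) == 89.3

    def test_event_table_accuracy_trace_over_total(self):
        acc = confusion_accuracy(ConfusionMatrix(TABLE7))
        assert acc == pytest.approx(100 * 49266 / 59024)
        assert acc == pytest.approx(83.47, abs=0.005)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_accuracy(ConfusionMatrix(np.zeros((4, 4), int)))

    def test_macro_f1_perfect_and_chance(self, rng):
        y = rng.integers(0, 4, 400)
        assert macro_f1(y, y) == 1.0
        assert macro_f1(rng.permutation(y), y) < 0.5
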