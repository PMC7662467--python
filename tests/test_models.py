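"""R-peak detection, IHR, LSTM event model, sleep-wake CNN."""
import dataclasses

import numpy as np
import pytest

from apneakit.core_io import SignalStream, SleepState
from apneakit.models import (EventModelConfig, ProbSeries, SleepWakeConfig,
                             decide_labels, detect_r_peaks, ihr, load_model,
                             predict_event_probs, save_model,
                             train_event_model, train_sleepwake)
from apneakit import nn


def render_ecg(peak_times, dur_s, fs=500.0, noise_sd=0.0, rng=None):
    t = np.arange(0, dur_s, 1 / fs)
    ecg = np.zeros(t.size)
    for rp in peak_times:
        ecg += np.exp(-0.5 * ((t - rp) / 0.012) ** 2)
    if noise_sd and rng is not None:
        ecg += rng.normal(0, noise_sd, t.size)
    return SignalStream(ecg, fs, 0.0, "ecg")


def match_peaks(found, truth, tol=0.05):
    hits = sum(1 for p in truth if np.any(np.abs(found - p) <= tol))
    fp = sum(1 for p in found if not np.any(np.abs(truth - p) <= tol))
    recall = hits / len(truth)
    precision = (len(found) - fp) / len(found) if len(found) else 0.0
    return recall, precision


class TestRPeaks:
    def test_impulse_train_with_noise(self, rng):
        truth = np.arange(0.5, 119.5, 1.0)
        ecg = render_ecg(truth, 120.0, noise_sd=0.1, rng=rng)
        found = detect_r_peaks(ecg)
        recall, precision = match_peaks(found, truth)
        assert recall >= 0.99 and precision >= 0.99

    def test_flat_ecg_gives_empty(self):
        assert detect_r_peaks(SignalStream(np.zeros(500 * 60), 500.0)).size == 0

    def test_alternating_rr_recovered(self):
        truth = np.cumsum([0.5] + [0.8, 1.0] * 70)
        truth = truth[truth < 120]
        found = detect_r_peaks(render_ecg(truth, 120.0))
        recall, precision = match_peaks(found, truth, tol=0.02)
        assert recall == 1.0 and precision == 1.0
        rr = np.diff(found)
        np.testing.assert_allclose(rr, np.diff(truth)[:rr.size], atol=0.02)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="100 Hz"):
            detect_r_peaks(SignalStream(np.zeros(600), 10.0))


class TestIhr:
    def test_uniform_rr_gives_60bpm(self):
        s = ihr(np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(s.samples, 60.0)
        assert s.rate_hz == 1.0

    def test_half_second_rr_gives_120bpm(self):
        s = ihr(np.arange(0, 10, 0.5))
        np.testing.assert_allclose(s.samples, 120.0)

    def test_closed_form_values(self):
        s = ihr(np.array([0.0, 0.8, 1.7]))
        # IHR defined from the second peak on: 60/0.8 then 60/0.9
        assert s.samples[0] == pytest.approx(75.0)
        assert s.samples[-1] == pytest.approx(60.0 / 0.9)

    def test_nonincreasing_rejected(self):
        with pytest.raises(ValueError):
            ihr(np.array([0.0, 1.0, 0.5]))
        with pytest.raises(ValueError, match="two R peaks"):
            ihr(np.array([1.0]))


def separable_windows(rng, n=80, frames=40):
    """Four classes with distinct mean feature levels."""
    y = rng.integers(0, 4, n)
    X = rng.normal(0, 0.1, (n, frames, 9))
    X[:, :, 0] += np.array([1.0, 1.4, 0.05, 0.7])[y][:, None]
    X[:, :, 1] += np.array([1.0, 1.4, 0.05, 0.7])[y][:, None]
    X[:, :, 5] -= np.array([0.0, 0.5, 0.5, 0.5])[y][:, None]
    return X, y


class TestEventModel:
    CFG = EventModelConfig(epochs=5, batches_per_epoch=10, batch_size=16, seed=3)

    def test_training_reduces_loss(self, rng):
        X, y = separable_windows(rng)
        m = train_event_model(X, y, self.CFG)
        assert m.loss_curve[-1] < m.loss_curve[0]

    def test_same_seed_identical_curves(self, rng):
        X, y = separable_windows(rng)
        m1 = train_event_model(X, y, self.CFG)
        m2 = train_event_model(X, y, self.CFG)
        assert m1.loss_curve == m2.loss_curve
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])

    def test_single_batch_overfit_reaches_100pct(self, rng):
        X, y = separable_windows(rng, n=10)
        y[:4] = np.arange(4)                         # all classes present
        cfg = dataclasses.replace(self.CFG, epochs=1, batches_per_epoch=500,
                                  batch_size=10, l2_beta=1e-4)
        m = train_event_model(X, y, cfg)
        pred = m.net.predict_proba(X).argmax(1)
        assert np.mean(pred == y) == 1.0

    def test_single_class_rejected(self, rng):
        X, _ = separable_windows(rng, n=12)
        with pytest.raises(ValueError, match="single class"):
            train_event_model(X, np.zeros(12, int), self.CFG)

    def test_parameter_count_fixed_by_architecture(self, rng):
        """(9, 80, 4) fixes the parameter count; N changes only sequence
        length, never the parameters."""
        net = nn.LstmClassifier(9, 80, 4, np.random.default_rng(0))
        expect = 9 * 320 + 80 * 320 + 320 + 80 * 4 + 4
        assert net.n_params == expect
        cfg_a = EventModelConfig(seq_span_s=20)
        cfg_b = EventModelConfig(seq_span_s=30)
        assert cfg_a.window_frames != cfg_b.window_frames

    def test_predict_rows_softmax_and_contract(self, rng):
        X, y = separable_windows(rng, n=30)
        m = train_event_model(X, y, self.CFG)
        import pandas as pd

        from apneakit.features import FEATURE_NAMES

        frames = pd.DataFrame(rng.normal(size=(120, 9)),
                              columns=list(FEATURE_NAMES))
        frames.insert(0, "t_s", 60 + 0.5 * np.arange(120))
        probs = predict_event_probs(m, frames)
        assert probs.probs.shape == (120, 4)
        np.testing.assert_allclose(probs.probs.sum(1), 1.0, atol=1e-9)
        permuted = frames[["t_s"] + list(FEATURE_NAMES[::-1])]
        with pytest.raises(ValueError, match="order"):
            predict_event_probs(m, permuted)
        with pytest.raises(ValueError, match="window"):
            predict_event_probs(m, frames.iloc[:10])

    def test_center_alignment_shifts_rows(self, rng):
        X, y = separable_windows(rng, n=30)
        m = train_event_model(X, y, self.CFG)
        import pandas as pd

        from apneakit.features import FEATURE_NAMES

        frames = pd.DataFrame(rng.normal(size=(100, 9)),
                              columns=list(FEATURE_NAMES))
        frames.insert(0, "t_s", 60 + 0.5 * np.arange(100))
        end = predict_event_probs(m, frames, align="end")
        cen = predict_event_probs(m, frames, align="center")
        np.testing.assert_array_equal(cen.probs[0], end.probs[20])

    def test_model_roundtrip(self, rng, tmp_path):
        X, y = separable_windows(rng, n=30)
        m = train_event_model(X, y, self.CFG)
        save_model(m, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.net.params["Wx"], m.net.params["Wx"])
        assert back.cfg == m.cfg


def test_label_shuffle_collapses_to_chance(rng):
    """Training on shuffled labels must destroy held-out skill -- guards
    against leakage between the train and test windows."""
    X, y = separable_windows(rng, n=160)
    shuffled = rng.permutation(y[:120])
    cfg = EventModelConfig(epochs=8, batches_per_epoch=10, batch_size=32,
                           seed=2)
    m = train_event_model(X[:120], shuffled, cfg)
    from apneakit.scoring import macro_f1

    f1 = macro_f1(m.net.predict_proba(X[120:]).argmax(1), y[120:])
    m_true = train_event_model(X[:120], y[:120], cfg)
    f1_true = macro_f1(m_true.net.predict_proba(X[120:]).argmax(1), y[120:])
    assert f1 < 0.5 < f1_true


class TestDecideLabels:
    def test_argmax_and_tie_order(self):
        probs = ProbSeries(np.array([0.0, 0.5, 1.0]),
                           np.array([[0.1, 0.7, 0.1, 0.1],
                                     [0.25, 0.25, 0.25, 0.25],
                                     [0.2, 0.2, 0.3, 0.3]]))
        labels = decide_labels(probs)
        assert labels.tolist() == [1, 0, 2]          # OSA; NOR by tie; CSA first

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProbSeries(np.array([0.0]), np.array([[0.5, 0.2, 0.2, 0.2]]))


def separable_sw_windows(rng, n=60):
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.normal(60.0, 2.0, (n, 2, 300))
    X[y == 1, 0] += 20.0                             # wake: faster heart rate
    X[y == 1, 0] += rng.normal(0, 6.0, (int(y.sum()), 300))
    return X, y


class TestSleepWake:
    CFG = SleepWakeConfig(train_steps=200, batch_size=32, seed=5)

    def test_block_halving_invariant(self):
        net = nn.SleepWakeNet(2, 300, 5, 10, 8, (1, 2), (20, 20), 2, 0.5,
                              np.random.default_rng(0))
        assert net.block_output_len <= 10
        assert net.flat_len == 10 * net.block_output_len

    def test_overfit_and_determinism(self, rng):
        X, y = separable_sw_windows(rng)
        m1 = train_sleepwake(X, y, self.CFG)
        m2 = train_sleepwake(X, y, self.CFG)
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])
        pred = (m1.net.predict_proba(X)[:, 1] >= 0.5).astype(int)
        assert np.mean(pred == y) == 1.0

    def test_short_window_rejected(self, rng):
        X = rng.normal(size=(10, 2, 100))
        with pytest.raises(ValueError, match="shorter"):
            train_sleepwake(X, np.arange(10) % 2, self.CFG)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2, 300))
        with pytest.raises(ValueError, match="single class"):
            train_sleepwake(X, np.zeros(10, int), self.CFG)

    def test_wake_wins_exact_tie(self, rng, sim_night):
        """An epoch whose wake output equals its sleep output is wake."""
        from apneakit.models import predict_sleepwake

        rec, _ = sim_night
        X, y = separable_sw_windows(rng)
        m = train_sleepwake(X, y, self.CFG)
        m.net.predict_proba = lambda X, batch=256: np.full((X.shape[0], 2), 0.5)
        hyp = predict_sleepwake(m, rec)
        assert all(e.state == SleepState.WAKE for e in hyp)
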