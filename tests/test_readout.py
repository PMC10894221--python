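"""FORCE/RLS readout: batch-ridge equivalence, stream construction,
evaluation plumbing."""

import numpy as np
import pytest

from oscsense.analysis import WaveformSet
from oscsense.decision import DMParams
from oscsense.readout import (
    ReadoutWeights,
    SampleStream,
    TrainingConfig,
    build_training_set,
    evaluate,
    extract_features,
    force_train,
)


def ridge_solution(X, Y, lam):
    """Closed-form ridge oracle with an augmented bias column."""
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    return np.linalg.solve(Xa.T @ Xa + lam * np.eye(Xa.shape[1]), Xa.T @ Y).T


def make_stream(X, Y, labels=None, names=None):
    n_cls = Y.shape[1]
    return SampleStream(
        X=X, Y=Y,
        labels=labels or ["c0"] * X.shape[0],
        class_labels=[f"c{i}" for i in range(n_cls)],
        feature_names=names or [f"f{i}" for i in range(X.shape[1])],
    )


class TestForceRlsOracle:
    @pytest.mark.parametrize("lam", [1.0, 10.0, 100.0])
    def test_equals_batch_ridge(self, lam, rng):
        """With update stride 1 on a finite stream, the recursive update is
        algebraically identical to ridge least squares at the same lambda."""
        X = rng.standard_normal((300, 6))
        Y = rng.standard_normal((300, 3))
        cfg = TrainingConfig(rls_lambda=lam)
        w, _ = force_train(make_stream(X, Y), cfg)
        W_oracle = ridge_solution(X, Y, lam)
        got = np.hstack([w.W, w.bias[:, None]])
        np.testing.assert_allclose(got, W_oracle, rtol=1e-6, atol=1e-9)

    def test_one_hot_indicator_inputs_reproduce_targets(self):
        """Constant one-hot channel indicators per class are fit exactly
        (matching the normal-equation solution)."""
        n_per = 60
        X = np.vstack([np.tile(np.eye(3)[i], (n_per, 1)) for i in range(3)])
        Y = np.vstack([np.tile(2 * np.eye(3)[i] - 1, (n_per, 1)) for i in range(3)])
        cfg = TrainingConfig(rls_lambda=1e-6)
        w, _ = force_train(make_stream(X, Y), cfg)
        preds = w.project(np.eye(3))
        np.testing.assert_allclose(preds, 2 * np.eye(3) - 1, atol=1e-3)

    def test_zero_inputs_leave_weights_move_bias(self):
        X = np.zeros((100, 4))
        Y = np.tile([0.5, -0.5], (100, 1))
        w, _ = force_train(make_stream(X, Y), TrainingConfig(rls_lambda=1.0))
        np.testing.assert_array_equal(w.W, 0.0)
        np.testing.assert_allclose(w.bias, [0.5, -0.5], atol=1e-2)

    def test_error_trace_decreases_on_learnable_stream(self, rng):
        X = rng.standard_normal((500, 5))
        W_true = rng.standard_normal((2, 5))
        Y = X @ W_true.T
        _, errors = force_train(make_stream(X, Y), TrainingConfig(rls_lambda=1.0))
        assert np.median(errors[-50:]) < 0.1 * np.median(errors[:50])

    def test_label_permutation_equivariance(self, rng):
        """Permuting target columns permutes the learned rows."""
        X = rng.standard_normal((200, 4))
        Y = rng.standard_normal((200, 3))
        perm = [2, 0, 1]
        w1, _ = force_train(make_stream(X, Y), TrainingConfig())
        w2, _ = force_train(make_stream(X, Y[:, perm]), TrainingConfig())
        np.testing.assert_allclose(w2.W, w1.W[perm], rtol=1e-10)


def sine_fixture(freq_phase_by_label, fs=2e6, duration=4e-4):
    t = np.arange(int(duration * fs)) / fs
    out = []
    for label, (f, phases) in freq_phase_by_label.items():
        channels = {
            str(i + 1): 1.0 + np.sin(2 * np.pi * (f * t - p / 360.0))
            for i, p in enumerate(phases)
        }
        out.append(WaveformSet(time=t, channels=channels, label=label))
    return out


class TestBuildTrainingSet:
    def fixture(self):
        return sine_fixture({
            "a": (50e3, [0, 120]),
            "b": (50e3, [0, 240]),
        })

    def test_sample_count_arithmetic(self):
        fix = self.fixture()
        cfg = TrainingConfig(train_window=1e-4, n_repeats=3, transient_cut=5e-5)
        stream = build_training_set(fix, cfg)
        # Window samples minus tap/smoothing trim, x repeats x labels.
        assert stream.X.shape[0] == stream.Y.shape[0] == len(stream.labels)
        per_trace = stream.X.shape[0] // (3 * 2)
        assert per_trace > 0.5 * 1e-4 * 2e6  # most of the window survives

    def test_exactly_one_positive_target_per_sample(self):
        stream = build_training_set(self.fixture(),
                                    TrainingConfig(train_window=1e-4, transient_cut=5e-5))
        assert np.all((stream.Y > 0).sum(axis=1) == 1)

    def test_seeded_shuffle_reproducible(self):
        fix = self.fixture()
        cfg = TrainingConfig(train_window=1e-4, transient_cut=5e-5, seed=4)
        a = build_training_set(fix, cfg)
        b = build_training_set(fix, cfg)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.labels == b.labels

    def test_trace_too_short_raises(self):
        fix = self.fixture()
        cfg = TrainingConfig(train_window=1.0, transient_cut=0.0)
        with pytest.raises(ValueError, match="trace-too-short"):
            build_training_set(fix, cfg)


class TestExtractFeatures:
    def test_lagged_products_encode_phase(self):
        """The mean lagged cross-product separates phase offsets that raw
        voltage means cannot."""
        a = sine_fixture({"x": (50e3, [0, 90])})[0]
        b = sine_fixture({"x": (50e3, [0, 270])})[0]
        Xa, names = extract_features(a, n_taps=1)
        Xb, _ = extract_features(b, n_taps=1)
        prod_cols = [i for i, n in enumerate(names) if "*" in n]
        lin_cols = [i for i, n in enumerate(names) if "*" not in n]
        lin_gap = np.abs(Xa[:, lin_cols].mean(0) - Xb[:, lin_cols].mean(0)).max()
        prod_gap = np.abs(Xa[:, prod_cols].mean(0) - Xb[:, prod_cols].mean(0)).max()
        assert prod_gap > 20 * max(lin_gap, 1e-6)

    def test_too_short_trace_raises(self):
        ws = sine_fixture({"x": (50e3, [0, 0])}, duration=1e-5)[0]
        with pytest.raises(ValueError, match="trace-too-short"):
            extract_features(ws, n_taps=3, tap_delay=10**6)


class TestEvaluate:
    def test_zero_weights_all_undecided(self):
        fix = sine_fixture({"a": (50e3, [0, 120]), "b": (50e3, [0, 240])})
        n_feat = extract_features(fix[0], n_taps=3)[0].shape[1]
        names = [f"f{i}" for i in range(n_feat)]
        w = ReadoutWeights(W=np.zeros((2, n_feat)), bias=np.zeros(2),
                           class_labels=["a", "b"], feature_names=names,
                           n_taps=3)
        cfg = TrainingConfig(train_window=1e-4, transient_cut=5e-5)
        report = evaluate(w, fix, DMParams(n_dm=2), cfg, seed=0)
        assert report.n_undecided == report.n_trials == 2
        assert report.accuracy == 0.0

    def test_trained_on_separable_sines_classifies(self):
        fix = sine_fixture({"a": (50e3, [0, 120]), "b": (50e3, [0, 240])})
        cfg = TrainingConfig(train_window=1.5e-4, transient_cut=5e-5)
        stream = build_training_set(fix, cfg)
        w, _ = force_train(stream, cfg)
        report = evaluate(w, fix, DMParams(n_dm=2), cfg, seed=0)
        assert report.accuracy == 1.0
        conf = report.confusion()
        assert conf["a"]["a"] == 1 and conf["b"]["b"] == 1

    def test_weights_json_round_trip(self, rng):
        w = ReadoutWeights(W=rng.standard_normal((2, 3)), bias=np.zeros(2),
                           class_labels=["a", "b"], feature_names=["x", "y", "z"],
                           n_taps=1, tap_delay=42)
        again = ReadoutWeights.from_json(w.to_json())
        np.testing.assert_allclose(again.W, w.W)
        assert again.tap_delay == 42
        assert again.class_labels == ["a", "b"]
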