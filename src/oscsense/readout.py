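"""FORCE-trained linear readout between oscillator waveforms and DM inputs.

The readout is a fully connected linear layer from waveform features to
one feedforward input per decision neuron, trained online by recursive
least squares (FORCE): per sample, the output error against a constant
target (+target_pos for the correct class, target_neg for the rest)
adjusts the weights through a running inverse-correlation matrix ``P``
initialized to ``I / rls_lambda``.  Processing a finite stream with
update_stride 1 is algebraically identical to ridge-regularized batch
least squares with the same lambda.

Phase is not a linear functional of instantaneous voltages alone, so the
feature vector augments the instantaneous channel voltages with delayed
taps (default two taps at quarter-period spacing), which makes phase
patterns linearly separable from as few as two or three channels.

Training windows are taken from the end of each trace (post-transient,
fully locked); test windows start at seeded random offsets near the
beginning, so evaluation runs on unseen samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from oscsense.analysis import AnalysisError, WaveformSet, detect_peaks, dominant_frequency
from oscsense.decision import DMInputTrace, DMParams, DMState, run_dm

__all__ = [
    "ReadoutWeights",
    "TrainingConfig",
    "EvaluationReport",
    "extract_features",
    "build_training_set",
    "force_train",
    "evaluate",
]

DEFAULT_TRANSIENT_CUT = 20e-6


@dataclass
class ReadoutWeights:
    """Linear combination layer: ``I = W @ features + bias``."""

    W: np.ndarray       # (n_classes, n_features)
    bias: np.ndarray    # (n_classes,)
    class_labels: list[str]
    feature_names: list[str]
    n_taps: int = 2
    tap_delay: int | None = None  # samples on the fixture's record grid

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.bias))):
            raise ValueError("weights must be finite")
        if self.W.shape != (len(self.class_labels), len(self.feature_names)):
            raise ValueError("weight shape does not match labels/features")

    def project(self, features: np.ndarray) -> np.ndarray:
        """(n_samples, n_features) -> (n_samples, n_classes)."""
        return features @ self.W.T + self.bias

    def to_json(self) -> str:
        return json.dumps({
            "W": self.W.tolist(), "bias": self.bias.tolist(),
            "class_labels": self.class_labels,
            "feature_names": self.feature_names, "n_taps": self.n_taps,
            "tap_delay": self.tap_delay,
        })

    @classmethod
    def from_json(cls, s: str) -> "ReadoutWeights":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class TrainingConfig:
    """FORCE training hyper-parameters.

    ``train_window`` seconds are taken from the end of each trace and
    repeated ``n_repeats`` times; ``rls_lambda`` is the ridge strength
    (P0 = I/lambda); ``update_stride`` thins the sample stream.
    """

    target_pos: float = 1.0
    target_neg: float = -1.0
    rls_lambda: float = 100.0
    update_stride: int = 1
    train_window: float = 40e-6
    n_repeats: int = 3
    transient_cut: float = DEFAULT_TRANSIENT_CUT
    n_taps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_pos > 0 > self.target_neg:
            raise ValueError("need target_pos > 0 > target_neg")
        if self.rls_lambda <= 0:
            raise ValueError("rls_lambda must be > 0")
        if self.update_stride < 1:
            raise ValueError("update_stride must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _tap_delay_samples(wset: WaveformSet) -> int:
    """A third of the reference channel's period, in samples (>= 1).

    With the default three taps the delayed copies span one full period,
    so the lag-T autocorrelation features double as a frequency
    discriminator (sharply sensitive to the common period).

    The period is measured from the median inter-peak interval (robust to
    harmonic ambiguity of the spectrum), with an FFT fallback.
    """
    ref = wset.channels[wset.channel_ids[0]]
    try:
        f = dominant_frequency(ref, wset.time)
        peaks = detect_peaks(ref, wset.time, min_distance=0.6 / f)
        period_samples = float(np.median(np.diff(peaks))) / wset.dt
    except AnalysisError:
        period_samples = max(wset.time.size / 8, 4)
    return max(int(round(period_samples / 3)), 1)


def extract_features(wset: WaveformSet, n_taps: int = 3,
                     tap_delay: int | None = None,
                     smooth: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Phase-sensitive feature vectors from a multichannel waveform.

    Per-channel standardized voltages, their ``n_taps`` delayed copies,
    and all lagged pairwise products of the standardized signals.  The
    products are the essential part: relaxation waveforms are invariant
    under time rescaling, so the *time averages* of raw (or delayed)
    voltages carry no phase information — but the average of
    ``z_i(t) * z_j(t - k*delay)`` is the lagged cross-correlation, which
    is exactly the phase pattern.  In hardware this is a mixer/phase
    detector in front of the linear layer.

    Returns ``(X, names)``; rows where a delayed tap would reach before
    the record are dropped.  ``tap_delay`` is in samples (default: quarter
    period of the first channel).
    """
    if tap_delay is None:
        tap_delay = _tap_delay_samples(wset)
    ids = wset.channel_ids
    n = wset.time.size
    start = n_taps * tap_delay
    if start >= n:
        raise ValueError("trace-too-short: delayed taps reach before the record")
    z = {}
    for cid in ids:
        v = wset.channels[cid]
        sd = v.std()
        z[cid] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    cols, names = [], []
    lagged = {}
    for k in range(n_taps + 1):
        off = k * tap_delay
        for cid in ids:
            lagged[(cid, k)] = z[cid][start - off : n - off]
            cols.append(lagged[(cid, k)])
            names.append(cid if k == 0 else f"{cid}-delay{k}")
    for k in range(n_taps + 1):
        for a, ci in enumerate(ids):
            for cj in ids[a:] if k == 0 else ids:
                if k == 0 and ci == cj:
                    continue  # z_i^2 at lag 0 is ~constant by construction
                cols.append(lagged[(ci, 0)] * lagged[(cj, k)])
                names.append(f"{ci}*{cj}" if k == 0 else f"{ci}*{cj}-delay{k}")
    X = np.column_stack(cols)
    if smooth is None:
        smooth = 3 * tap_delay  # about one oscillation period
    if smooth > 1 and X.shape[0] > smooth:
        # Post-mixer low-pass: a boxcar over ~one period strips the
        # oscillation ripple so constant targets are fittable without
        # least-squares shrinkage.
        c = np.cumsum(X, axis=0)
        X = (c[smooth:] - c[:-smooth]) / smooth
    return X, names


@dataclass
class SampleStream:
    """Concatenated training stream: features, targets, per-sample labels."""

    X: np.ndarray          # (n_samples, n_features)
    Y: np.ndarray          # (n_samples, n_classes)
    labels: list[str]      # per-sample true label
    class_labels: list[str]
    feature_names: list[str]
    tap_delay: int | None = None


def build_training_set(fixture: list[WaveformSet], cfg: TrainingConfig) -> SampleStream:
    """Trailing-window training stream from a labeled fixture.

    Per trace: drop the transient, take the trailing ``train_window``,
    repeat it ``n_repeats`` times, and attach constant target vectors
    (+target_pos at the true class, target_neg elsewhere).  Traces are
    concatenated in seeded shuffled order.
    """
    class_labels = sorted({w.label for w in fixture if w.label is not None})
    if not class_labels:
        raise ValueError("fixture has no labeled traces")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(fixture))
    xs, ys, labs = [], [], []
    feature_names: list[str] | None = None
    tap_delay: int | None = None
    for idx in order:
        wset = fixture[idx]
        if wset.duration <= cfg.transient_cut + cfg.train_window:
            raise ValueError(
                f"trace-too-short: needs > {cfg.transient_cut + cfg.train_window:.3g} s, "
                f"has {wset.duration:.3g} s"
            )
        t_start = wset.time[-1] - cfg.train_window
        win = wset.window(t_start)
        if tap_delay is None:
            tap_delay = _tap_delay_samples(win)
        X, names = extract_features(win, n_taps=cfg.n_taps, tap_delay=tap_delay)
        if feature_names is None:
            feature_names = names
        y = np.full(len(class_labels), cfg.target_neg)
        y[class_labels.index(wset.label)] = cfg.target_pos
        X_rep = np.tile(X, (cfg.n_repeats, 1))
        xs.append(X_rep)
        ys.append(np.tile(y, (X_rep.shape[0], 1)))
        labs.extend([wset.label] * X_rep.shape[0])
    return SampleStream(
        X=np.vstack(xs), Y=np.vstack(ys), labels=labs,
        class_labels=class_labels, feature_names=feature_names or [],
        tap_delay=tap_delay,
    )


def force_train(stream: SampleStream, cfg: TrainingConfig) -> tuple[ReadoutWeights, np.ndarray]:
    """Recursive-least-squares FORCE training over a sample stream.

    Standard RLS with an augmented bias feature: for each used sample
    ``x``, ``k = P x / (1 + x' P x)``, ``e = W x + b - target``,
    ``W <- W - e k'``, ``P <- P - k (x' P)``.  Returns the final weights
    and the per-update error magnitudes; raises on divergence (running
    error exceeding 1e3 times its initial value).
    """
    if stream.X.shape[0] == 0:
        raise ValueError("empty stream")
    n_feat = stream.X.shape[1]
    n_cls = stream.Y.shape[1]
    dim = n_feat + 1  # +1 bias
    P = np.eye(dim) / cfg.rls_lambda
    W = np.zeros((n_cls, dim))
    errors = []
    err0 = None
    for i in range(0, stream.X.shape[0], cfg.update_stride):
        x = np.append(stream.X[i], 1.0)
        Px = P @ x
        k = Px / (1.0 + x @ Px)
        e = W @ x - stream.Y[i]
        W -= np.outer(e, k)
        P -= np.outer(k, Px)
        mag = float(np.linalg.norm(e))
        errors.append(mag)
        if err0 is None and mag > 0:
            err0 = mag
        if err0 is not None and mag > 1e3 * err0:
            raise FloatingPointError(
                f"divergence: error {mag:.3g} exceeds 1e3 x initial {err0:.3g}"
            )
    return (
        ReadoutWeights(
            W=W[:, :-1], bias=W[:, -1],
            class_labels=stream.class_labels,
            feature_names=stream.feature_names,
            n_taps=cfg.n_taps,
            tap_delay=stream.tap_delay,
        ),
        np.asarray(errors),
    )


@dataclass
class EvaluationReport:
    """Per-trial predictions plus confusion counts and accuracy."""

    records: list[dict]
    class_labels: list[str]

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def n_correct(self) -> int:
        return sum(1 for r in self.records if r["predicted"] == r["true"])

    @property
    def n_undecided(self) -> int:
        return sum(1 for r in self.records if r["predicted"] is None)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials if self.records else 0.0

    def confusion(self) -> dict[str, dict[str, int]]:
        table: dict[str, dict[str, int]] = {
            t: {p: 0 for p in self.class_labels + ["undecided"]}
            for t in self.class_labels
        }
        for r in self.records:
            pred = r["predicted"] if r["predicted"] is not None else "undecided"
            table[r["true"]][pred] += 1
        return table

    def to_json(self) -> str:
        return json.dumps({
            "records": self.records,
            "class_labels": self.class_labels,
            "accuracy": self.accuracy,
            "n_undecided": self.n_undecided,
            "confusion": self.confusion(),
        }, indent=2)


def evaluate(
    weights: ReadoutWeights,
    fixture: list[WaveformSet],
    dm: DMParams,
    cfg: TrainingConfig | None = None,
    test_window: float | None = None,
    seed: int = 1,
) -> EvaluationReport:
    """Classify each trial through the readout and the decision network.

    Test windows start at seeded random offsets near the beginning of each
    trace (just after the transient), disjoint by construction from the
    trailing training windows.  An undecided run counts as incorrect.
    """
    cfg = cfg or TrainingConfig()
    test_window = test_window if test_window is not None else cfg.train_window
    rng = np.random.default_rng(seed)
    if dm.n_dm != len(weights.class_labels):
        raise ValueError("DM size does not match the number of classes")
    records = []
    for wset in fixture:
        span = wset.duration - cfg.transient_cut - test_window
        # Random start offset in the first half of the usable span.
        offset = cfg.transient_cut + rng.uniform(0.0, max(span / 2, 0.0))
        win = wset.window(wset.time[0] + offset,
                          wset.time[0] + offset + test_window)
        X, _ = extract_features(win, n_taps=weights.n_taps,
                                tap_delay=weights.tap_delay)
        I = weights.project(X)
        trace = DMInputTrace(time=np.arange(X.shape[0]) * dm.dt_dm, I=I)
        result = run_dm(trace, dm, DMState.zeros(dm.n_dm))
        pred = weights.class_labels[result.winner] if result.winner is not None else None
        records.append({
            "true": wset.label,
            "predicted": pred,
            **result.winner_report(weights.class_labels),
        })
    return EvaluationReport(records=records, class_labels=weights.class_labels)
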