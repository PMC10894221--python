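"""Capacitive sensor models and labeled fixture generation.

Two sensor kinds are modelled, both of which *increase* capacitance with
stimulus: pressure sensors (pressing compresses the dielectric gap) and
stretch sensors (capacitance proportional to elongation).  A stimulus
pattern maps per-node stimulus magnitudes onto per-node parallel
capacitances, which shift the oscillators' natural frequencies; the
coupled network then encodes the pattern as a phase pattern.

:func:`generate_fixture` runs the full pipeline for a task (touch /
gesture / 8-mode), producing labeled, reproducible waveform sets with
additive measurement noise, plus enough provenance to regenerate them.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, replace

import numpy as np

from oscsense.analysis import WaveformSet
from oscsense.device import sample_devices
from oscsense.oscillator import ONNConfig, simulate
from oscsense.units import parse_si

__all__ = [
    "SensorModel",
    "StimulusPattern",
    "capacitance",
    "gesture_to_stimuli",
    "task_labels",
    "label_to_stimuli",
    "generate_fixture",
    "write_fixture",
    "read_fixture",
]

GESTURES = ("rock", "paper", "scissor")
MODE8_LABELS = tuple(f"{i:03b}" for i in range(8))

#: Default measurement-noise signal-to-noise ratio, dB.
DEFAULT_SNR_DB = 30.0

_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class SensorModel:
    """One capacitive sensor.

    ``capacitance = c_base * (1 + eps) * (1 + gain * stimulus)`` with
    ``eps ~ Normal(0, jitter_sigma)`` drawn once per trial.  ``gain`` is
    the relative capacitance increase per unit stimulus (dimensionless);
    stimulus 0 is rest, 1 is a full press / full bend.
    """

    kind: str = "pressure"  # or "stretch"
    c_base: float = 2.85e-9
    gain: float = 1.2
    jitter_sigma: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_base", parse_si(self.c_base))
        if self.kind not in ("pressure", "stretch"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if self.c_base <= 0:
            raise ValueError("c_base must be > 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "c_base": self.c_base,
                "gain": self.gain, "jitter_sigma": self.jitter_sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        return cls(**d)


@dataclass(frozen=True)
class StimulusPattern:
    """Per-node stimulus magnitudes plus the task label."""

    s: tuple[float, ...]
    label: str

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.s):
            raise ValueError("stimulus magnitudes must be >= 0")


def capacitance(
    sensor: SensorModel, stimulus: float, rng: np.random.Generator | None = None
) -> float:
    """Trial capacitance of a sensor under a stimulus (farads).

    Strictly increasing in the stimulus at fixed jitter.  Non-positive
    draws (pathological jitter) are resampled a bounded number of times.
    """
    if stimulus < 0:
        raise ValueError("stimulus must be >= 0")
    base_factor = 1.0 + sensor.gain * stimulus
    if sensor.jitter_sigma == 0 or rng is None:
        return sensor.c_base * base_factor
    for _ in range(_MAX_RESAMPLES):
        eps = sensor.jitter_sigma * rng.standard_normal()
        c = sensor.c_base * (1.0 + eps) * base_factor
        if c > 0:
            return c
    raise ValueError("negative-capacitance: jitter drove capacitance <= 0 repeatedly")


def gesture_to_stimuli(gesture: str, bent_level: float = 1.0) -> StimulusPattern:
    """Map a gesture (or a 3-bit mode string) onto per-finger bend levels.

    Fingers are ordered (thumb, forefinger, middle).  Rock bends all
    three, paper extends all three, scissor extends forefinger and middle
    with the thumb bent.  A bit string maps bit=1 to bent.
    """
    if gesture == "rock":
        return StimulusPattern(s=(bent_level,) * 3, label="rock")
    if gesture == "paper":
        return StimulusPattern(s=(0.0, 0.0, 0.0), label="paper")
    if gesture == "scissor":
        return StimulusPattern(s=(bent_level, 0.0, 0.0), label="scissor")
    if len(gesture) >= 1 and set(gesture) <= {"0", "1"}:
        return StimulusPattern(
            s=tuple(bent_level if b == "1" else 0.0 for b in gesture), label=gesture
        )
    raise ValueError(f"unknown-gesture: {gesture!r}")


def task_labels(task: str, n_nodes: int = 3) -> tuple[str, ...]:
    if task == "touch":
        return ("no-touch", "touch")
    if task == "gesture":
        return GESTURES
    if task == "modes8":
        return tuple(format(i, f"0{n_nodes}b") for i in range(2 ** n_nodes))
    raise ValueError(f"unknown task {task!r}")


def label_to_stimuli(task: str, label: str, n_nodes: int, bent_level: float = 1.0) -> StimulusPattern:
    """Stimulus vector for one task label.

    Touch drives only the sensory node (node index 1; node 0 is the fixed
    reference).  Gesture and modes8 drive all three fingers.
    """
    if task == "touch":
        if label == "touch":
            return StimulusPattern(s=(0.0, 1.0) + (0.0,) * (n_nodes - 2), label=label)
        if label == "no-touch":
            return StimulusPattern(s=(0.0,) * n_nodes, label=label)
        raise ValueError(f"unknown touch label {label!r}")
    if task in ("gesture", "modes8"):
        pat = gesture_to_stimuli(label, bent_level=bent_level)
        if len(pat.s) != n_nodes:
            raise ValueError(f"label {label!r} implies {len(pat.s)} nodes, config has {n_nodes}")
        return pat
    raise ValueError(f"unknown task {task!r}")


def _apply_noise(wset: WaveformSet, snr_db: float, rng: np.random.Generator) -> WaveformSet:
    """Additive white Gaussian measurement noise at the given SNR."""
    noisy = {}
    for k, v in wset.channels.items():
        p_sig = np.mean((v - v.mean()) ** 2)
        sigma = np.sqrt(p_sig / (10 ** (snr_db / 10.0)))
        noisy[k] = v + sigma * rng.standard_normal(v.size)
    return WaveformSet(time=wset.time, channels=noisy, meta=wset.meta, label=wset.label)


def generate_fixture(
    task: str,
    onn_template: ONNConfig,
    sensors: list[SensorModel],
    n_trials: int = 1,
    seed: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
    bent_level: float = 1.0,
    d2d_vth_range: tuple[float, float] | None = None,
    d2d_vhold_range: tuple[float, float] | None = None,
) -> list[WaveformSet]:
    """Run the task's full label set through the coupled network.

    For every label and trial: draw per-sensor jitter (and, when the d2d
    ranges are given, fresh device thresholds), set each node's parallel
    capacitance from its sensor, simulate, add measurement noise, and
    attach the label.  Deterministic under a fixed seed.

    Touch semantics: node 0 is the reference neuron whose capacitor is
    fixed (its sensor still defines the touched-state capacitance via
    stimulus 0), the remaining nodes carry sensors.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_nodes = len(onn_template.nodes)
    if len(sensors) != n_nodes:
        raise ValueError("need one sensor model per node")
    labels = task_labels(task, n_nodes)
    rng = np.random.default_rng(seed)
    out: list[WaveformSet] = []
    for label in labels:
        pattern = label_to_stimuli(task, label, n_nodes, bent_level=bent_level)
        for trial in range(n_trials):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trial_rng = np.random.default_rng(trial_seed)
            nodes = []
            if d2d_vth_range is not None or d2d_vhold_range is not None:
                devices = sample_devices(
                    n_nodes,
                    vth_range=d2d_vth_range or (onn_template.nodes[0].device.v_th,) * 2,
                    vhold_range=d2d_vhold_range or (onn_template.nodes[0].device.v_hold,) * 2,
                    seed=int(trial_rng.integers(0, 2**31 - 1)),
                    template=onn_template.nodes[0].device,
                )
            else:
                devices = [n.device for n in onn_template.nodes]
            for node, sensor, stim, dev in zip(onn_template.nodes, sensors, pattern.s, devices):
                c = capacitance(sensor, stim, trial_rng)
                nodes.append(replace(node, c_parallel=c, device=dev))
            cfg = ONNConfig(
                nodes=nodes,
                coupling=dict(onn_template.coupling),
                v_dd=onn_template.v_dd,
                pulse_duration=onn_template.pulse_duration,
                init_voltages=onn_template.init_voltages,
                dt=onn_template.dt,
                record_stride=onn_template.record_stride,
                seed=int(trial_rng.integers(0, 2**31 - 1)),
            )
            try:
                wset = simulate(cfg)
            except Exception as exc:
                raise type(exc)(f"label {label!r} trial {trial}: {exc}") from exc
            if snr_db is not None and np.isfinite(snr_db):
                wset = _apply_noise(wset, snr_db, trial_rng)
            wset.label = label
            wset.meta = dict(wset.meta)
            wset.meta.update({"task": task, "label": label, "trial": trial,
                              "trial_seed": trial_seed, "snr_db": snr_db})
            out.append(wset)
    return out


def write_fixture(fixture: list[WaveformSet], out_dir: str | pathlib.Path) -> None:
    """Persist a fixture as CSV waveforms plus a manifest JSON."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, wset in enumerate(fixture):
        name = f"trial_{i:03d}_{wset.label}.csv"
        wset.to_csv(out / name)
        manifest.append({"file": name, "label": wset.label, "meta": wset.meta})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_fixture(in_dir: str | pathlib.Path) -> list[WaveformSet]:
    """Load a fixture directory written by :func:`write_fixture`."""
    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    out = []
    for entry in manifest:
        out.append(WaveformSet.from_csv(src / entry["file"],
                                        meta=entry.get("meta", {}),
                                        label=entry["label"]))
    return out
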