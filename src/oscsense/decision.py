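"""Mean-field winner-take-all decision network.

A reduced attractor model of perceptual decision making: each of the
``n_dm`` neurons represents one category and carries a slow synaptic
gating variable ``s_i`` in [0, 1].  The synaptic input combines
self-excitation, uniform mutual inhibition, and the feedforward drive
from the readout layer::

    x_i = j_e * s_i + sum_{j != i} j_m * s_j + I_i          (j_e >= 0, j_m <= 0)
    r_i = (beta / gamma) * ln(1 + exp((x_i - theta) / alpha))
    tau_s * ds_i/dt = -s_i + gamma * (1 - s_i) * r_i

The softplus-log activation is computed overflow-safely.  The slow
dynamics integrate evidence over time; mutual inhibition makes the neurons
compete until one ends with a high activity (the winner) while the others
are suppressed — the network's classification output.

Time here is the DM clock, decoupled from circuit time: oscillator traces
are resampled onto the DM grid before being fed in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DMParams",
    "DMState",
    "DMInputTrace",
    "activation",
    "dm_step",
    "run_dm",
    "DMResult",
]


@dataclass(frozen=True)
class DMParams:
    """Decision-network constants.

    Defaults are a working point of the reduced mean-field family chosen
    so that the network is a clean winner-take-all for feedforward inputs
    of order one (the scale the trained readout produces): with two
    constant inputs differing by 10%, exactly one neuron ends above
    ``r_dec`` while the others are suppressed below a quarter of the
    winner's activity.
    """

    n_dm: int = 2
    j_e: float = 2.0
    j_m: float = -1.0
    alpha: float = 0.3
    beta: float = 0.7
    gamma: float = 0.641
    theta: float = 1.0
    tau_s: float = 100.0
    dt_dm: float = 0.5
    r_dec: float = 2.5

    def __post_init__(self) -> None:
        if self.n_dm < 1:
            raise ValueError("n_dm must be >= 1")
        if self.j_e < 0:
            raise ValueError("j_e must be >= 0 (self-excitation)")
        if self.j_m > 0:
            raise ValueError("j_m must be <= 0 (mutual inhibition)")
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must be > 0")
        if not self.tau_s >= 50 * self.dt_dm:
            raise ValueError("tau_s must be >= 50 * dt_dm (slow dynamics)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_dm", "j_e", "j_m", "alpha", "beta", "gamma",
            "theta", "tau_s", "dt_dm", "r_dec")}

    @classmethod
    def from_dict(cls, d: dict) -> "DMParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class DMState:
    """Synaptic variables, activities, inputs, and the DM-clock time."""

    s: np.ndarray
    r: np.ndarray
    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.s < 0) or np.any(self.s > 1):
            raise ValueError("s_i must lie in [0, 1]")
        if np.any(self.r < 0):
            raise ValueError("r_i must be >= 0")

    @classmethod
    def zeros(cls, n: int) -> "DMState":
        return cls(s=np.zeros(n), r=np.zeros(n), x=np.zeros(n), t=0.0)


@dataclass
class DMInputTrace:
    """Feedforward input I_i(t) per DM neuron on a uniform DM-clock grid."""

    time: np.ndarray
    I: np.ndarray  # (n_samples, n_dm)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.I = np.atleast_2d(np.asarray(self.I, dtype=float))
        if self.I.shape[0] != self.time.size:
            raise ValueError("I must have one row per time sample")


def activation(x, params: DMParams):
    """Softplus-log activation (beta/gamma) * ln(1 + exp((x - theta)/alpha)).

    For large arguments the linear asymptote (beta/gamma)*(x - theta)/alpha
    is used, which is exact to double precision beyond (x-theta)/alpha > 30.
    """
    z = (np.asarray(x, dtype=float) - params.theta) / params.alpha
    out = np.where(z > 30.0, z, np.log1p(np.exp(np.minimum(z, 30.0))))
    out = params.beta / params.gamma * out
    return float(out) if np.isscalar(x) else out


def dm_step(state: DMState, I_t: np.ndarray, params: DMParams) -> DMState:
    """One Euler step of the slow synaptic dynamics.

    Computes the instantaneous input and activity, then advances ``s`` by
    ``dt_dm``.  The dynamics preserve [0, 1] for exact integration; the
    clamp only guards against Euler overshoot.
    """
    s = state.s
    I_t = np.asarray(I_t, dtype=float)
    total_s = s.sum()
    # x_i = j_e s_i + j_m * sum_{j != i} s_j + I_i
    x = params.j_e * s + params.j_m * (total_s - s) + I_t
    r = activation(x, params)
    ds = (-s + params.gamma * (1.0 - s) * r) / params.tau_s
    s_new = np.clip(s + params.dt_dm * ds, 0.0, 1.0)
    if not (np.all(np.isfinite(s_new)) and np.all(np.isfinite(r))):
        raise FloatingPointError("nonfinite-state in decision network")
    return DMState(s=s_new, r=np.asarray(r), x=x, t=state.t + params.dt_dm)


@dataclass
class DMResult:
    """Trajectory and verdict of one decision run."""

    time: np.ndarray
    s: np.ndarray  # (n_steps, n_dm)
    r: np.ndarray
    winner: int | None  # index, or None for "undecided"

    @property
    def decided(self) -> bool:
        return self.winner is not None

    def winner_report(self, labels: list[str] | None = None) -> dict:
        final_r = self.r[-1]
        return {
            "winner": None if self.winner is None
            else (labels[self.winner] if labels else int(self.winner)),
            "final_activities": final_r.tolist(),
            "margin": float(np.sort(final_r)[-1] - np.sort(final_r)[-2])
            if final_r.size > 1 else float(final_r[0]),
        }


def run_dm(
    inputs: DMInputTrace, params: DMParams, init: DMState | None = None
) -> DMResult:
    """Integrate the decision network over an input trace and read the winner.

    The input trace is resampled onto the DM clock by linear interpolation.
    The winner is the unique neuron whose final activity exceeds ``r_dec``
    (argmax if several, provided the argmax is strict); an exact tie or no
    neuron above threshold reports undecided (``winner=None``).
    """
    n = params.n_dm
    if inputs.I.shape[1] != n:
        raise ValueError(f"input trace has {inputs.I.shape[1]} columns, params.n_dm={n}")
    state = init if init is not None else DMState.zeros(n)
    t_end = float(inputs.time[-1])
    n_steps = max(int(np.ceil(t_end / params.dt_dm)), 1)
    grid = np.arange(n_steps + 1) * params.dt_dm
    I_grid = np.column_stack([
        np.interp(grid, inputs.time, inputs.I[:, k]) for k in range(n)
    ])
    ts = np.empty(n_steps + 1)
    ss = np.empty((n_steps + 1, n))
    rs = np.empty((n_steps + 1, n))
    ts[0], ss[0], rs[0] = state.t, state.s, state.r
    for i in range(n_steps):
        state = dm_step(state, I_grid[i], params)
        ts[i + 1], ss[i + 1], rs[i + 1] = state.t, state.s, state.r
    final_r = rs[-1]
    above = np.flatnonzero(final_r > params.r_dec)
    winner: int | None = None
    if above.size == 1:
        winner = int(above[0])
    elif above.size > 1:
        best = np.argsort(final_r)[::-1]
        if final_r[best[0]] > final_r[best[1]]:  # strict argmax, ties undecided
            winner = int(best[0])
    return DMResult(time=ts, s=ss, r=rs, winner=winner)
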