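"""Capacitively coupled VO2 relaxation-oscillator network simulator.

A single node is a series resistor ``r_load`` from the supply ``v_dd`` into
the parallel combination of a sensing capacitor ``c_parallel`` and a VO2
threshold switch.  In the insulating state the capacitor charges toward the
HRS voltage-divider level; when the device voltage reaches ``v_th`` the
switch fires, the capacitor discharges through ``r_on`` until ``v_hold``,
and the cycle repeats — a classic relaxation oscillation.

Nodes are coupled through capacitors between their output terminals, which
adds ``C_ij * d(V_j - V_i)/dt`` displacement-current terms.  Collecting the
derivatives gives the linear-implicit form::

    M dV/dt = b(V),   b_i = (v_dd - V_i)/r_load_i - V_i/R_i(state)

with ``M`` the capacitance matrix (diagonal ``c_i + sum_j C_ij``,
off-diagonal ``-C_ij``).  ``M`` is symmetric and strictly diagonally
dominant, hence invertible; it is factorized once per run.

Integration is fixed-step explicit midpoint (RK2) with switching events
located by bisection inside the step, so that the event timing does not
bias the oscillation period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from oscsense.analysis import WaveformSet
from oscsense.device import DeviceParams
from oscsense.units import parse_si

__all__ = [
    "OscillatorNode",
    "ONNConfig",
    "NonOscillatingError",
    "check_oscillates",
    "analytic_period",
    "build_capacitance_matrix",
    "startup_init",
    "simulate",
]

#: Measured upper working frequency of the physical device; the simulator
#: warns (but proceeds) when a node's analytic frequency exceeds it.
MAX_DEVICE_FREQUENCY = 2.6e6


class NonOscillatingError(ValueError):
    """The node cannot self-oscillate at the given supply."""


class StepTooLargeError(RuntimeError):
    """A voltage moved by more than the allowed fraction of the hysteresis
    window in a single step; decrease dt."""


@dataclass(frozen=True)
class OscillatorNode:
    """One relaxation-oscillator node.

    ``r_load`` is the series resistor from the supply, ``c_parallel`` the
    sensing capacitance in parallel with the device.
    """

    node_id: str
    r_load: float
    c_parallel: float
    device: DeviceParams = field(default_factory=DeviceParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_load", parse_si(self.r_load))
        object.__setattr__(self, "c_parallel", parse_si(self.c_parallel))
        if self.r_load <= 0:
            raise ValueError("r_load must be > 0")
        if self.c_parallel <= 0:
            raise ValueError("c_parallel must be > 0")


@dataclass
class ONNConfig:
    """Full description of one coupled-oscillator run.

    Parameters
    ----------
    nodes:
        Ordered list of oscillator nodes.
    coupling:
        Map ``(id_i, id_j) -> farads``; treated as symmetric with zero
        diagonal.  Missing pairs are uncoupled.
    v_dd:
        Supply voltage, volts (default 10 V).
    pulse_duration:
        Length of the supply pulse, seconds (default 300 us).
    init_voltages:
        Per-node initial voltages; ``None`` selects the deterministic
        start-up divider pattern of :func:`startup_init`.
    dt:
        Integration step; ``None`` selects min-RC/200 where min-RC is the
        smallest ``(r_load || r_on) * c_parallel`` over nodes (the
        discharge phase is the stiffest).
    record_stride:
        Record every this-many integration steps.
    seed:
        Seed for cycle-to-cycle threshold jitter (and randomized init).
    """

    nodes: list[OscillatorNode]
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    v_dd: float = 10.0
    pulse_duration: float = 300e-6
    init_voltages: dict[str, float] | None = None
    dt: float | None = None
    record_stride: int = 4
    seed: int = 0
    force: bool = False          # skip the oscillation-feasibility gate
    max_step_fraction: float = 0.5  # of (v_th - v_hold), per step

    def __post_init__(self) -> None:
        self.v_dd = parse_si(self.v_dd)
        self.coupling = {k: parse_si(v) for k, v in self.coupling.items()}
        if self.v_dd <= 0:
            raise ValueError("v_dd must be > 0")
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node_ids must be unique")
        for (i, j), c in self.coupling.items():
            if i == j:
                raise ValueError("coupling diagonal must be zero")
            if c < 0:
                raise ValueError("coupling capacitances must be >= 0")
            if i not in ids or j not in ids:
                raise ValueError(f"coupling references unknown node ({i}, {j})")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.init_voltages is not None:
            for nid, v in self.init_voltages.items():
                if not 0 <= v <= self.v_dd:
                    raise ValueError(f"init voltage for {nid} outside [0, v_dd]")

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def coupling_value(self, i: str, j: str) -> float:
        return self.coupling.get((i, j), self.coupling.get((j, i), 0.0))

    def resolved_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        min_rc = min(
            (n.r_load * n.device.r_on / (n.r_load + n.device.r_on)) * n.c_parallel
            for n in self.nodes
        )
        return min_rc / 200.0

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "r_load": n.r_load,
                    "c_parallel": n.c_parallel,
                    "device": n.device.to_dict(),
                }
                for n in self.nodes
            ],
            "coupling": [[i, j, c] for (i, j), c in sorted(self.coupling.items())],
            "v_dd": self.v_dd,
            "pulse_duration": self.pulse_duration,
            "init_voltages": self.init_voltages,
            "dt": self.dt,
            "record_stride": self.record_stride,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ONNConfig":
        nodes = [
            OscillatorNode(
                node_id=nd["node_id"],
                r_load=nd["r_load"],
                c_parallel=nd["c_parallel"],
                device=DeviceParams.from_dict(nd["device"]),
            )
            for nd in d["nodes"]
        ]
        coupling = {(i, j): c for i, j, c in d.get("coupling", [])}
        init = d.get("init_voltages")
        return cls(
            nodes=nodes,
            coupling=coupling,
            v_dd=d.get("v_dd", 10.0),
            pulse_duration=d.get("pulse_duration", 300e-6),
            init_voltages=dict(init) if init else None,
            dt=d.get("dt"),
            record_stride=d.get("record_stride", 4),
            seed=d.get("seed", 0),
        )


def check_oscillates(node: OscillatorNode, v_dd: float) -> tuple[bool, str]:
    """Self-oscillation feasibility of one uncoupled node.

    The HRS voltage-divider level must exceed ``v_th`` (otherwise the
    device never fires: stuck HRS) and the LRS level must fall below
    ``v_hold`` (otherwise the metallic state never releases: stuck LRS).
    Returns ``(ok, diagnostic)``.
    """
    d = node.device
    v_hrs = v_dd * d.r_off / (node.r_load + d.r_off)
    v_lrs = v_dd * d.r_on / (node.r_load + d.r_on)
    msgs = []
    if not v_hrs > d.v_th:
        msgs.append(
            f"stuck HRS: divider level {v_hrs:.3g} V <= v_th {d.v_th:.3g} V"
        )
    if not v_lrs < d.v_hold:
        msgs.append(
            f"stuck LRS: divider level {v_lrs:.3g} V >= v_hold {d.v_hold:.3g} V"
        )
    if msgs:
        return False, "; ".join(msgs)
    return True, "oscillates"


def analytic_period(
    node: OscillatorNode, v_dd: float, include_dead_times: bool = False
) -> float:
    """Closed-form period of one uncoupled relaxation oscillator.

    Each half-cycle is an exact first-order RC relaxation toward the
    Thevenin level of the corresponding device state::

        charge    (HRS): V8 = v_dd*r_off/(r_load+r_off),
                         tau = (r_load || r_off) * c,
                         t = tau * ln[(V8 - v_hold) / (V8 - v_th)]
        discharge (LRS): same with r_on, relaxing from v_th down to v_hold.

    Raises :class:`NonOscillatingError` when the feasibility conditions
    fail.  Warns when the frequency exceeds the device's measured maximum.
    """
    ok, why = check_oscillates(node, v_dd)
    if not ok:
        raise NonOscillatingError(why)
    d = node.device
    c = node.c_parallel

    v_inf_off = v_dd * d.r_off / (node.r_load + d.r_off)
    tau_off = (node.r_load * d.r_off / (node.r_load + d.r_off)) * c
    t_charge = tau_off * math.log((v_inf_off - d.v_hold) / (v_inf_off - d.v_th))

    v_inf_on = v_dd * d.r_on / (node.r_load + d.r_on)
    tau_on = (node.r_load * d.r_on / (node.r_load + d.r_on)) * c
    t_discharge = tau_on * math.log((d.v_th - v_inf_on) / (d.v_hold - v_inf_on))

    period = t_charge + t_discharge
    if include_dead_times:
        period += d.t_sw_on + d.t_sw_off
    if 1.0 / period > MAX_DEVICE_FREQUENCY:
        warnings.warn(
            f"analytic frequency {1.0/period:.3g} Hz exceeds the device's "
            f"measured maximum of {MAX_DEVICE_FREQUENCY:.2g} Hz",
            stacklevel=2,
        )
    return period


def build_capacitance_matrix(config: ONNConfig) -> np.ndarray:
    """Capacitance matrix M of the coupled network (farads, N x N).

    ``M[i, i] = c_parallel_i + sum_j C_ij`` and ``M[i, j] = -C_ij``.  With
    all couplings zero it is ``diag(c_parallel)``.
    """
    ids = config.node_ids
    n = len(ids)
    m = np.zeros((n, n))
    for a, node in enumerate(config.nodes):
        if node.c_parallel <= 0:
            raise ValueError(f"singular matrix: node {node.node_id} has c <= 0")
        m[a, a] = node.c_parallel
    for a in range(n):
        for b in range(a + 1, n):
            c = config.coupling_value(ids[a], ids[b])
            if c > 0:
                m[a, a] += c
                m[b, b] += c
                m[a, b] -= c
                m[b, a] -= c
    return m


def startup_init(config: ONNConfig) -> dict[str, float]:
    """Deterministic start-up voltages emulating the divider start circuit.

    The physical network uses a resistive-divider start-up stage so that
    the phase mode reached after coupling is reproducible across power-ups.
    Here node ``i`` of ``N`` (1-based, in config order) starts at
    ``v_hold + i/(N+1) * (v_th - v_hold)``: pairwise distinct, strictly
    below threshold, independent of the seed.

    If ``config.init_voltages`` is the string-free randomized mode (i.e.
    caller wants seeded draws), use :func:`randomized_init` instead.
    """
    n = len(config.nodes)
    out: dict[str, float] = {}
    for i, node in enumerate(config.nodes, start=1):
        d = node.device
        out[node.node_id] = d.v_hold + (i / (n + 1)) * (d.v_th - d.v_hold)
    return out


def randomized_init(config: ONNConfig, seed: int) -> dict[str, float]:
    """Seeded uniform initial voltages in [0, v_hold] per node."""
    rng = np.random.default_rng(seed)
    return {
        node.node_id: float(rng.uniform(0.0, node.device.v_hold))
        for node in config.nodes
    }


def _conductances(config: ONNConfig) -> tuple[np.ndarray, np.ndarray]:
    g_load = np.array([1.0 / n.r_load for n in config.nodes])
    return g_load, g_load * config.v_dd


@njit(cache=True)
def _rk2_step(m_inv, i_src, g_tot, v, h):  # pragma: no cover - jitted
    k1 = m_inv @ (i_src - v * g_tot)
    vm = v + 0.5 * h * k1
    k2 = m_inv @ (i_src - vm * g_tot)
    return v + h * k2


@njit(cache=True)
def _any_crossing(v, is_lrs, vth, vhold):  # pragma: no cover - jitted
    for k in range(v.shape[0]):
        if is_lrs[k]:
            if v[k] <= vhold[k]:
                return True
        elif v[k] >= vth[k]:
            return True
    return False


@njit(cache=True)
def _integrate(
    m_inv, g_load, i_src, g_on, g_off,
    vth_nom, vhold_nom, sig_vth, sig_vhold,
    t_sw_on, t_sw_off, v0, dt, n_steps, record_stride, seed, max_dv,
):  # pragma: no cover - jitted
    """Fixed-step RK2 with bisection-refined switching events.

    Status codes: 0 ok, 1 step-too-large, 2 event-loop guard tripped,
    3 threshold redraw failed.
    """
    np.random.seed(seed)
    n = v0.shape[0]
    v = v0.copy()
    is_lrs = np.zeros(n, np.bool_)
    g_dev = g_off.copy()
    g_tot = g_load + g_dev
    vth = vth_nom.copy()
    vhold = vhold_nom.copy()
    pend_until = np.full(n, np.inf)
    pend_lrs = np.zeros(n, np.bool_)
    has_dead = False
    for k in range(n):
        if t_sw_on[k] > 0.0 or t_sw_off[k] > 0.0:
            has_dead = True
    n_rec = n_steps // record_stride + 1
    v_rec = np.empty((n_rec, n))
    v_rec[0] = v
    rec_i = 1
    time_tol = dt / 100.0
    t = 0.0
    status = 0
    for step in range(n_steps):
        remaining = dt
        guard = 0
        while remaining > 1e-12 * dt:
            guard += 1
            if guard > 100000:
                status = 2
                break
            if has_dead:
                for k in range(n):
                    if pend_until[k] <= t:
                        g_dev[k] = g_on[k] if pend_lrs[k] else g_off[k]
                        g_tot[k] = g_load[k] + g_dev[k]
                        pend_until[k] = np.inf
            v_try = _rk2_step(m_inv, i_src, g_tot, v, remaining)
            if not _any_crossing(v_try, is_lrs, vth, vhold):
                for k in range(n):
                    if abs(v_try[k] - v[k]) > max_dv:
                        status = 1
                v = v_try
                t += remaining
                remaining = 0.0
                break
            # Bisect the sub-step length to the earliest crossing.
            lo = 0.0
            hi = remaining
            while hi - lo > time_tol:
                mid = 0.5 * (lo + hi)
                if _any_crossing(_rk2_step(m_inv, i_src, g_tot, v, mid), is_lrs, vth, vhold):
                    hi = mid
                else:
                    lo = mid
            v = _rk2_step(m_inv, i_src, g_tot, v, hi)
            t += hi
            remaining -= hi
            # Switch every node that crossed, in config node order.
            for k in range(n):
                crossed = (v[k] <= vhold[k]) if is_lrs[k] else (v[k] >= vth[k])
                if not crossed:
                    continue
                going_lrs = not is_lrs[k]
                is_lrs[k] = going_lrs
                if sig_vth[k] > 0.0 or sig_vhold[k] > 0.0:
                    ok = False
                    nvth = vth_nom[k]
                    nvhold = vhold_nom[k]
                    for _ in range(100):
                        nvth = vth_nom[k] * (1.0 + sig_vth[k] * np.random.standard_normal())
                        nvhold = vhold_nom[k] * (1.0 + sig_vhold[k] * np.random.standard_normal())
                        if nvhold < nvth:
                            ok = True
                            break
                    if not ok:
                        status = 3
                        break
                    vth[k] = nvth
                    vhold[k] = nvhold
                tsw = t_sw_on[k] if going_lrs else t_sw_off[k]
                if tsw > 0.0:
                    pend_until[k] = t + tsw
                    pend_lrs[k] = going_lrs
                else:
                    g_dev[k] = g_on[k] if going_lrs else g_off[k]
                    g_tot[k] = g_load[k] + g_dev[k]
            if status != 0:
                break
        t = (step + 1) * dt
        if (step + 1) % record_stride == 0:
            v_rec[rec_i] = v
            rec_i += 1
        if status != 0:
            break
    return v_rec, rec_i, status


def simulate(config: ONNConfig) -> WaveformSet:
    """Integrate the coupled network over the supply pulse.

    Fixed-step explicit midpoint on ``M dV/dt = b(V)`` with the device
    states frozen within a step; any threshold crossing detected after a
    step is refined by bisection on the step length to within dt/100
    before the device switches, and integration resumes from the refined
    instant.  Simultaneous crossings switch in config node order.

    Returns a :class:`~oscsense.analysis.WaveformSet` with one channel per
    node, sampled every ``record_stride`` steps.
    """
    for node in config.nodes:
        ok, why = check_oscillates(node, config.v_dd)
        if not ok and not config.force:
            raise NonOscillatingError(f"node {node.node_id}: {why}")

    ids = config.node_ids
    dt = config.resolved_dt()

    m = build_capacitance_matrix(config)
    m_inv = np.linalg.inv(m)
    g_load, i_src = _conductances(config)

    init = config.init_voltages if config.init_voltages is not None else startup_init(config)
    v0 = np.array([init[i] for i in ids], dtype=float)

    devs = [nd.device for nd in config.nodes]
    max_dv = config.max_step_fraction * min(d.v_th - d.v_hold for d in devs)
    n_steps = int(math.ceil(config.pulse_duration / dt))

    v_rec, rec_i, status = _integrate(
        m_inv, g_load, i_src,
        np.array([1.0 / d.r_on for d in devs]),
        np.array([1.0 / d.r_off for d in devs]),
        np.array([d.v_th for d in devs]),
        np.array([d.v_hold for d in devs]),
        np.array([d.sigma_vth_c2c for d in devs]),
        np.array([d.sigma_vhold_c2c for d in devs]),
        np.array([d.t_sw_on for d in devs]),
        np.array([d.t_sw_off for d in devs]),
        v0, dt, n_steps, config.record_stride,
        config.seed % (2**31 - 1), max_dv,
    )
    if status == 1:
        raise StepTooLargeError(
            f"a voltage moved more than {max_dv:.3g} V in one step; decrease dt"
        )
    if status == 2:
        raise RuntimeError("event-handling loop failed to make progress")
    if status == 3:
        raise ValueError("could not draw effective thresholds with v_hold < v_th")

    v_rec = v_rec[:rec_i]
    t_rec = np.arange(rec_i) * (dt * config.record_stride)
    return WaveformSet(
        time=t_rec,
        channels={nid: v_rec[:, a] for a, nid in enumerate(ids)},
        meta={"config": config.to_dict(), "dt": dt},
    )
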