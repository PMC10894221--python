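"""Compact behavioural model of a volatile VO2 threshold switch.

The device is a two-state resistive switch with voltage hysteresis: in the
high-resistance (insulating) state it switches to the low-resistance
(metallic) state when the voltage across it reaches ``v_th``; in the
low-resistance state it drops back once the voltage falls to ``v_hold``.
Because ``v_hold < v_th`` the switch is hysteretic, which is what turns an
RC charging circuit into a relaxation oscillator.

Cycle-to-cycle threshold jitter and device-to-device parameter spread are
modelled as independent random draws; both default to the measured scale of
monocrystalline VO2 devices (relative std of a few 1e-4 cycle-to-cycle,
and thresholds spread over roughly half a volt device-to-device).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Phase",
    "DeviceParams",
    "DeviceState",
    "resistance",
    "step_state",
    "sample_devices",
    "NOMINAL",
]

#: Saturated switching times measured on the real device; kept as named
#: constants because the default model runs with zero dead time.
T_SW_ON_SATURATED = 115e-9
T_SW_OFF_SATURATED = 90e-9

#: Printed device-to-device spread of the switching thresholds.
VTH_D2D_RANGE = (3.55, 4.10)
VHOLD_D2D_RANGE = (1.52, 1.96)

_MAX_REDRAWS = 100


class Phase(str, enum.Enum):
    """Resistive phase of the switch."""

    HRS = "HRS"  # insulating, R_off
    LRS = "LRS"  # metallic, R_on


@dataclass(frozen=True)
class DeviceParams:
    """Electrical parameters of one threshold switch.

    Parameters
    ----------
    v_th:
        Threshold voltage for the insulator-to-metal transition, volts.
    v_hold:
        Minimum voltage that sustains the metallic state, volts.
        Must satisfy ``v_hold < v_th``.
    r_on, r_off:
        Metallic (LRS) and insulating (HRS) resistances, ohms.
    t_sw_on, t_sw_off:
        Finite switching times, seconds, modelled as a pure dead time
        during which the resistance holds its pre-transition value.
        Default 0 (instantaneous switching).
    sigma_vth_c2c, sigma_vhold_c2c:
        Relative cycle-to-cycle standard deviations of the two thresholds;
        effective thresholds are redrawn at every transition.
    """

    v_th: float = 4.0
    v_hold: float = 1.7
    r_on: float = 300.0
    r_off: float = 20e3
    t_sw_on: float = 0.0
    t_sw_off: float = 0.0
    sigma_vth_c2c: float = 0.00021
    sigma_vhold_c2c: float = 0.00013

    def __post_init__(self) -> None:
        if not self.v_hold < self.v_th:
            raise ValueError(f"v_hold ({self.v_hold}) must be < v_th ({self.v_th})")
        if not 0 < self.r_on < self.r_off:
            raise ValueError(f"need 0 < r_on < r_off, got {self.r_on}, {self.r_off}")
        if self.t_sw_on < 0 or self.t_sw_off < 0:
            raise ValueError("switching times must be >= 0")
        if self.sigma_vth_c2c < 0 or self.sigma_vhold_c2c < 0:
            raise ValueError("jitter sigmas must be >= 0")

    def to_dict(self) -> dict:
        return {
            "v_th": self.v_th, "v_hold": self.v_hold,
            "r_on": self.r_on, "r_off": self.r_off,
            "t_sw_on": self.t_sw_on, "t_sw_off": self.t_sw_off,
            "sigma_vth_c2c": self.sigma_vth_c2c,
            "sigma_vhold_c2c": self.sigma_vhold_c2c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DeviceParams":
        return cls.from_dict(json.loads(s))


#: Nominal parameter set: round-number thresholds inside the printed
#: device-to-device spans, resistances at the printed HRS/LRS values.
NOMINAL = DeviceParams()


@dataclass(frozen=True)
class DeviceState:
    """Instantaneous state: phase plus this cycle's jittered thresholds."""

    phase: Phase = Phase.HRS
    effective_vth: float = NOMINAL.v_th
    effective_vhold: float = NOMINAL.v_hold

    def __post_init__(self) -> None:
        if not self.effective_vhold < self.effective_vth:
            raise ValueError(
                f"effective_vhold ({self.effective_vhold}) must be < "
                f"effective_vth ({self.effective_vth})"
            )


def initial_state(params: DeviceParams, phase: Phase = Phase.HRS) -> DeviceState:
    """Fresh state with nominal (unjittered) effective thresholds."""
    return DeviceState(phase=phase, effective_vth=params.v_th, effective_vhold=params.v_hold)


def resistance(state: DeviceState, params: DeviceParams) -> float:
    """Resistance in ohms for the current phase."""
    return params.r_off if state.phase is Phase.HRS else params.r_on


def _draw_thresholds(params: DeviceParams, rng: np.random.Generator) -> tuple[float, float]:
    """Draw jittered effective thresholds, enforcing v_hold < v_th."""
    if params.sigma_vth_c2c == 0 and params.sigma_vhold_c2c == 0:
        return params.v_th, params.v_hold
    for _ in range(_MAX_REDRAWS):
        vth = params.v_th * (1.0 + params.sigma_vth_c2c * rng.standard_normal())
        vhold = params.v_hold * (1.0 + params.sigma_vhold_c2c * rng.standard_normal())
        if vhold < vth:
            return vth, vhold
    raise ValueError(
        "could not draw effective thresholds with v_hold < v_th after "
        f"{_MAX_REDRAWS} attempts (sigmas too large?)"
    )


def step_state(
    state: DeviceState,
    v_device: float,
    params: DeviceParams,
    rng: np.random.Generator | None = None,
) -> DeviceState:
    """Advance the hysteretic switch by one voltage observation.

    HRS switches to LRS iff ``v_device >= effective_vth``; LRS switches to
    HRS iff ``v_device <= effective_vhold``; anywhere strictly inside the
    hysteresis window the state is unchanged.  On each transition new
    effective thresholds are drawn for the next cycle.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if state.phase is Phase.HRS and v_device >= state.effective_vth:
        vth, vhold = _draw_thresholds(params, rng)
        return DeviceState(phase=Phase.LRS, effective_vth=vth, effective_vhold=vhold)
    if state.phase is Phase.LRS and v_device <= state.effective_vhold:
        vth, vhold = _draw_thresholds(params, rng)
        return DeviceState(phase=Phase.HRS, effective_vth=vth, effective_vhold=vhold)
    return state


def sample_devices(
    n: int,
    vth_range: tuple[float, float] = VTH_D2D_RANGE,
    vhold_range: tuple[float, float] = VHOLD_D2D_RANGE,
    seed: int = 0,
    template: DeviceParams = NOMINAL,
) -> list[DeviceParams]:
    """Draw ``n`` device parameter sets emulating device-to-device spread.

    ``v_th`` and ``v_hold`` are drawn independently and uniformly from the
    given closed intervals (defaults: the measured spread over 40 devices).
    All other fields are copied from ``template``.  Deterministic under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo_t, hi_t = vth_range
    lo_h, hi_h = vhold_range
    if hi_t < lo_t or hi_h < lo_h:
        raise ValueError("ranges must be non-empty (lo <= hi)")
    rng = np.random.default_rng(seed)
    out: list[DeviceParams] = []
    for _ in range(n):
        for _attempt in range(_MAX_REDRAWS):
            vth = rng.uniform(lo_t, hi_t)
            vhold = rng.uniform(lo_h, hi_h)
            if vhold < vth:
                out.append(replace(template, v_th=vth, v_hold=vhold))
                break
        else:
            raise ValueError(
                f"could not draw v_hold < v_th from ranges {vth_range}, "
                f"{vhold_range} after {_MAX_REDRAWS} attempts"
            )
    return out
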