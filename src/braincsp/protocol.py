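"""Activation protocol: stimulation window, CBF trapezoid, venous balloon.

The in-vivo human activation scenario stimulates the tissue for 900 s.
Presynaptic activity enters as constant sodium source terms (reactions
40/41) during the window.  Cerebral blood flow rises trapezoidally by
40% with a 2 s onset lag and returns after a 10 s offset lag; the rise
ramp lasts 30 s and, the published description being silent on the fall,
the fall ramp defaults to the symmetric 30 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .parameters import ParameterSet


@dataclass(frozen=True)
class ScenarioProtocol:
    t_start: float = 0.0          # activation onset, s
    t_end: float = 900.0          # activation offset, s
    vstim_n: float = 0.15290      # neuronal stimulation rate, mM/s
    vstim_g: float = 0.059823     # astrocytic (EAAT) stimulation rate, mM/s
    cbf_gain: float = 1.4         # plateau CBF relative to baseline
    onset_lag: float = 2.0        # s
    offset_lag: float = 10.0      # s
    ramp: float = 30.0            # rise ramp duration, s
    fall_ramp: float = 30.0       # fall ramp duration, s
    t_sim_end: float = 10000.0    # simulation horizon, s
    grid_dt: float = 1.0          # default output spacing, s

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end < self.t_sim_end:
            raise ValueError("need t_start < t_end < t_sim_end")
        if min(self.onset_lag, self.offset_lag, self.ramp, self.fall_ramp) < 0:
            raise ValueError("lags and ramps must be non-negative")

    def replace(self, **kw) -> "ScenarioProtocol":
        return replace(self, **kw)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Times where the forcing has kinks; integration is split here."""
        return (
            self.t_start,
            self.t_start + self.onset_lag,
            self.t_start + self.onset_lag + self.ramp,
            self.t_end,
            self.t_end + self.offset_lag,
            self.t_end + self.offset_lag + self.fall_ramp,
        )


def null_protocol(t_sim_end: float = 1000.0) -> ScenarioProtocol:
    """Baseline protocol: no stimulation, constant baseline CBF.

    The (inert) activation window is squeezed inside the horizon so any
    simulation end time is valid.
    """
    return ScenarioProtocol(vstim_n=0.0, vstim_g=0.0, cbf_gain=1.0,
                            t_end=min(900.0, 0.5 * t_sim_end),
                            t_sim_end=t_sim_end)


def stimulation_inputs(t: float, protocol: ScenarioProtocol) -> tuple[float, float]:
    """Presynaptic source rates (R40, R41) at time t (mM/s)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if protocol.t_start <= t < protocol.t_end:
        return protocol.vstim_n, protocol.vstim_g
    return 0.0, 0.0


def cbf_profile(t: float, protocol: ScenarioProtocol, params: ParameterSet) -> float:
    """Cerebral blood flow F(t) in 1/s: trapezoid between F0 and gain*F0."""
    F0 = params.F0
    F1 = protocol.cbf_gain * F0
    rise0 = protocol.t_start + protocol.onset_lag
    fall0 = protocol.t_end + protocol.offset_lag
    if t <= rise0:
        return F0
    if t < rise0 + protocol.ramp:
        return F0 + (F1 - F0) * (t - rise0) / protocol.ramp
    if t <= fall0:
        return F1
    if t < fall0 + protocol.fall_ramp:
        return F1 + (F0 - F1) * (t - fall0) / protocol.fall_ramp
    return F0


def venous_outflow(Vv: float, F_now: float, params: ParameterSet) -> float:
    """Venous balloon outflow (1/s), closed-form solution.

    The balloon law
    Fout = F0 [ (Vv/Vv0)^(1/alpha) + tau_v/Vv0 (Vv/Vv0)^(-1/2) dVv/dt ]
    is implicit because dVv/dt = F(t) - Fout; substituting and solving
    the linear scalar equation gives
    Fout = (F0 v^(1/alpha) + c F) / (1 + c), c = F0 tau_v / (Vv0 sqrt(v)).
    """
    if Vv <= 0:
        raise ValueError("Vv must be positive")
    p = params
    v = Vv / p.Vv0
    c = p.F0 * p.tau_v / (p.Vv0 * math.sqrt(v))
    return (p.F0 * v ** (1.0 / p.alpha_v) + c * F_now) / (1.0 + c)
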