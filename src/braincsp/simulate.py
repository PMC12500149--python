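"""Scenario integration: baseline steady state and the activation run.

The system is stiff (timescales span milliseconds to hours), so the
scenario is integrated with an implicit BDF method using the analytic
Jacobian, split into segments at the protocol breakpoints so the solver
never steps across a forcing kink.  Dense output provides states at
arbitrary analysis times without re-integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import BrainModel
from .parameters import ParameterSet
from .protocol import ScenarioProtocol, cbf_profile, null_protocol
from .state import N_STATES, STATE_INDEX, STATE_NAMES, resting_state


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last accepted time t={last_time:.6g} s)")
        self.last_time = last_time


def steady_state(params: ParameterSet | None = None,
                 y0: np.ndarray | None = None,
                 tol: float = 1e-12) -> np.ndarray:
    """Baseline fixed point of the unstimulated model.

    Newton-refines the published resting values (which are rounded and,
    for the fast glycolytic intermediates, only indicative) to the exact
    root of g(y) = 0 under baseline blood flow and no stimulation.
    """
    model = BrainModel(params, null_protocol())
    if y0 is None:
        y0 = resting_state()
    # Pre-relax fast transients so Newton starts in the attraction basin.
    pre = solve_ivp(lambda t, y: model.vector_field(y, t), (0.0, 200.0), y0,
                    method="BDF", jac=lambda t, y: model.jacobian(y, t),
                    rtol=1e-10, atol=1e-12)
    if not pre.success:
        raise IntegrationError("pre-relaxation failed", pre.t[-1])
    sol = root(lambda y: model.vector_field(y, 0.0), pre.y[:, -1],
               jac=lambda y: model.jacobian(y, 0.0), method="hybr",
               tol=tol)
    if not sol.success:
        raise RuntimeError(f"steady-state solve failed: {sol.message}")
    resid = np.max(np.abs(model.vector_field(sol.x, 0.0)))
    if resid > 1e-9:
        raise RuntimeError(f"steady-state residual too large: {resid}")
    return sol.x


@dataclass
class Trajectory:
    """Time-ordered solution of a scenario with dense-output access."""

    t: np.ndarray                 # output grid, s
    y: np.ndarray                 # states, shape (len(t), N_STATES)
    params: ParameterSet
    protocol: ScenarioProtocol
    _segments: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def model(self) -> BrainModel:
        return BrainModel(self.params, self.protocol)

    def state(self, t: float) -> np.ndarray:
        """State at an arbitrary time via the solver's dense output."""
        for (t0, t1, interp) in self._segments:
            if t0 <= t <= t1:
                return np.asarray(interp(t))
        raise ValueError(f"t={t} outside the integrated range")

    def cbf(self, t: float) -> float:
        return cbf_profile(t, self.protocol, self.params)

    def to_frame(self):
        """Tidy table: time, the 29 variables, F(t) and BOLD.

        The BOLD baseline (dHb0, Vv0) is taken from the trajectory's own
        initial state, so a run started at rest reads BOLD(0) = 0.
        """
        import pandas as pd

        from .closures import bold_signal

        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time", self.t)
        df["F"] = [self.cbf(t) for t in self.t]
        p0 = self.params.replace(dHb0=float(self.y[0, STATE_INDEX["dHb"]]),
                                 Vv0=float(self.y[0, STATE_INDEX["Vv"]]))
        df["BOLD"] = bold_signal(df["dHb"].to_numpy(), df["Vv"].to_numpy(), p0)
        return df


def default_analysis_grid(protocol: ScenarioProtocol,
                          dt_fine: float = 1.0, t_fine_end: float = 1000.0,
                          dt_coarse: float = 10.0) -> np.ndarray:
    """1 s spacing through the activation epoch and early recovery,
    10 s spacing for the slow tail."""
    t_fine_end = min(t_fine_end, protocol.t_sim_end)
    fine = np.arange(0.0, t_fine_end, dt_fine)
    coarse = np.arange(t_fine_end, protocol.t_sim_end + 0.5 * dt_coarse,
                       dt_coarse)
    return np.unique(np.concatenate([fine, coarse]))


def integrate_scenario(protocol: ScenarioProtocol | None = None,
                       params: ParameterSet | None = None,
                       initial_state: np.ndarray | None = None,
                       t_grid: np.ndarray | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the activation scenario and sample it on the analysis grid.

    ``initial_state`` defaults to the refined baseline steady state (the
    published resting values at full precision).
    """
    protocol = protocol if protocol is not None else ScenarioProtocol()
    params = params if params is not None else ParameterSet()
    model = BrainModel(params, protocol)
    if initial_state is None:
        initial_state = steady_state(params)
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (N_STATES,):
        raise ValueError("initial state has wrong shape")
    if t_grid is None:
        t_grid = default_analysis_grid(protocol)

    edges = sorted({0.0, protocol.t_sim_end,
                    *[b for b in protocol.breakpoints
                      if 0.0 < b < protocol.t_sim_end]})
    segments = []
    y = y0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        # The stimulation is piecewise constant: freeze it at the segment
        # midpoint so solver evaluations at segment edges cannot sample
        # the wrong side of the discontinuity.  CBF is continuous and is
        # evaluated at the (clamped) solver time.
        from .protocol import stimulation_inputs
        vn, vg = stimulation_inputs(0.5 * (t0 + t1), protocol)

        def rhs(t, yy, vn=vn, vg=vg, t1=t1):
            F = cbf_profile(min(t, t1), protocol, params)
            return model.vector_field_at(yy, F, vn, vg)

        def jac(t, yy, vn=vn, vg=vg, t1=t1):
            F = cbf_profile(min(t, t1), protocol, params)
            return model.jacobian_at(yy, F, vn, vg)

        sol = solve_ivp(rhs, (t0, t1), y, method="BDF", jac=jac,
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   sol.t[-1])
        segments.append((t0, t1, sol.sol))
        y = sol.y[:, -1]

    t_grid = np.asarray(t_grid, dtype=float)
    Y = np.empty((len(t_grid), N_STATES))
    seg_i = 0
    for i, t in enumerate(t_grid):
        while t > segments[seg_i][1] and seg_i < len(segments) - 1:
            seg_i += 1
        Y[i] = segments[seg_i][2](t)
    return Trajectory(t=t_grid, y=Y, params=params, protocol=protocol,
                      _segments=segments)
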