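"""Vector field and Jacobians of the brain energy metabolism model.

dy/dt = g(y) = S @ R(y, t) with S the constant stoichiometric matrix and
R the 67 unidirectional rates.  The Jacobian is assembled from analytic
rate gradients, J = S @ dR/dy, and decomposes exactly into per-reaction
contributions grad(S_k R_k) = outer(S[:, k], dR_k/dy), the quantities
the timescale participation index is built from.
"""

from __future__ import annotations

import numpy as np

from . import _kinetics
from .parameters import ParameterSet
from .protocol import ScenarioProtocol, cbf_profile, stimulation_inputs
from .registry import LABEL_INDEX, N_REACTIONS
from .state import N_STATES
from .stoichiometry import stoichiometric_matrix


class BrainModel:
    """The 29-variable model bound to a parameter set and protocol."""

    def __init__(self, params: ParameterSet | None = None,
                 protocol: ScenarioProtocol | None = None):
        self.params = params if params is not None else ParameterSet()
        self.protocol = protocol if protocol is not None else ScenarioProtocol()
        self.S = stoichiometric_matrix(self.params)

    # -- forcing -------------------------------------------------------
    def inputs(self, t: float) -> tuple[float, float, float]:
        """(F, vstim_n, vstim_g) at time t."""
        F = cbf_profile(t, self.protocol, self.params)
        vn, vg = stimulation_inputs(t, self.protocol)
        return F, vn, vg

    # -- explicit-input variants (forcing supplied by the caller) -------
    def rates_at(self, y, F: float, vn: float, vg: float) -> np.ndarray:
        return _kinetics.rates(np.asarray(y, float), F, vn, vg, self.params)

    def vector_field_at(self, y, F: float, vn: float, vg: float) -> np.ndarray:
        return self.S @ self.rates_at(y, F, vn, vg)

    def jacobian_at(self, y, F: float, vn: float, vg: float) -> np.ndarray:
        return self.S @ _kinetics.rate_gradients(np.asarray(y, float), F, vn,
                                                 vg, self.params)

    # -- rates and vector field ----------------------------------------
    def rates(self, y: np.ndarray, t: float) -> np.ndarray:
        """All unidirectional rates (mM/s) in registry order."""
        y = np.asarray(y, dtype=float)
        if np.any(y < -1e-9):  # tolerate integrator-level roundoff only
            raise ValueError("negative concentration in state")
        F, vn, vg = self.inputs(t)
        return _kinetics.rates(y, F, vn, vg, self.params)

    def vector_field(self, y: np.ndarray, t: float) -> np.ndarray:
        return self.S @ self.rates(y, t)

    # -- Jacobians ------------------------------------------------------
    def rate_gradients(self, y: np.ndarray, t: float) -> np.ndarray:
        """Analytic dR/dy, shape (K, N)."""
        F, vn, vg = self.inputs(t)
        return _kinetics.rate_gradients(np.asarray(y, float), F, vn, vg,
                                        self.params)

    def jacobian(self, y: np.ndarray, t: float) -> np.ndarray:
        """Analytic N x N Jacobian of the vector field."""
        return self.S @ self.rate_gradients(y, t)

    def jacobian_fd(self, y: np.ndarray, t: float,
                    rel_step: float = 1e-5) -> np.ndarray:
        """Finite-difference Jacobian (test oracle).

        Central differences with one Richardson extrapolation step
        (O(h^4)), needed because some rate laws (the NADH shuttles) have
        near-singular curvature that plain central differences resolve
        poorly."""
        y = np.asarray(y, dtype=float)

        def central(h_scale):
            J = np.empty((N_STATES, N_STATES))
            for j in range(N_STATES):
                h = h_scale * max(abs(y[j]), 1e-3)
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                J[:, j] = (self.vector_field(yp, t)
                           - self.vector_field(ym, t)) / (2 * h)
            return J

        J1 = central(rel_step)
        J2 = central(rel_step / 2)
        return (4.0 * J2 - J1) / 3.0

    def jacobian_per_reaction(self, y: np.ndarray, t: float,
                              label: str) -> np.ndarray:
        """grad(S_k R_k) for one unidirectional reaction."""
        k = LABEL_INDEX[label]  # raises KeyError for unknown labels
        grad = self.rate_gradients(y, t)[k]
        return np.outer(self.S[:, k], grad)

    def per_reaction_jacobians(self, y: np.ndarray, t: float) -> np.ndarray:
        """All grad(S_k R_k) stacked, shape (K, N, N); sums to the Jacobian."""
        grads = self.rate_gradients(y, t)
        return self.S.T[:, :, None] * grads[:, None, :]


# -- thin functional wrappers (the module-level spec surface) -----------

def compute_rates(state, params, t, protocol) -> np.ndarray:
    return BrainModel(params, protocol).rates(state, t)


def vector_field(state, params, t, protocol) -> np.ndarray:
    return BrainModel(params, protocol).vector_field(state, t)


def jacobian_full(state, params, t, protocol) -> np.ndarray:
    return BrainModel(params, protocol).jacobian(state, t)


def jacobian_per_reaction(state, params, t, protocol, label) -> np.ndarray:
    return BrainModel(params, protocol).jacobian_per_reaction(state, t, label)
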