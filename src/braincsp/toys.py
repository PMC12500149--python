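"""Toy multiscale systems with known eigenstructure and slow manifolds.

These small ODE systems exercise every CSP diagnostic against closed
forms that are independent of the eigen-decomposition code: a linear
two-timescale system whose basis vectors and indices are hand-derived,
and the reversible enzyme (Michaelis-Menten) system whose fast mode
expresses the binding/unbinding partial equilibrium and whose slow
manifold is the classical quasi-steady-state complex concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class ToySystem:
    """A small reaction system in the same (S, R, grad R) form as the
    full model, plus analytic reference quantities."""

    dim: int
    labels: tuple[str, ...]
    S: np.ndarray                                  # (dim, K)
    rates: Callable[[np.ndarray], np.ndarray]      # R(y), (K,)
    rate_gradients: Callable[[np.ndarray], np.ndarray]  # dR/dy, (K, dim)
    eps: float                                     # timescale-gap ratio
    reference: dict = field(default_factory=dict)  # analytic callables/values

    def vector_field(self, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(np.asarray(y, float))

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rate_gradients(np.asarray(y, float))

    def solve(self, y0: np.ndarray, t: np.ndarray) -> np.ndarray:
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda _, y: self.vector_field(y), (t[0], t[-1]),
                        np.asarray(y0, float), t_eval=t, method="BDF",
                        jac=lambda _, y: self.jacobian(y),
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(sol.message)
        return sol.y.T


def linear_two_scale_system(eps: float, angle: float = math.pi / 2) -> ToySystem:
    """2-D linear system with eigenvalues -1/eps (fast) and -1 (slow).

    The right eigenvectors are v_fast = (1, 0) and
    v_slow = (cos(angle), sin(angle)); angle = pi/2 makes them
    orthogonal.  Written as two "reactions", one per eigendirection:
    S_k = v_k with scalar rate R_k = lambda_k * (b_k . y), so each
    reaction generates exactly one timescale and the analytic TPI of
    mode n is a unit vector on reaction n.
    """
    if not 0.0 < eps < 1.0:
        raise ValueError("eps must lie in (0, 1)")
    lam_fast, lam_slow = -1.0 / eps, -1.0
    V = np.array([[1.0, math.cos(angle)],
                  [0.0, math.sin(angle)]])
    B = np.linalg.inv(V)

    Smat = V.copy()

    def rates(y):
        return np.array([lam_fast * (B[0] @ y), lam_slow * (B[1] @ y)])

    def grads(y):
        return np.array([lam_fast * B[0], lam_slow * B[1]])

    ref = {
        "eigenvalues": np.array([lam_fast, lam_slow]),
        "timescales": np.array([eps, 1.0]),
        "right": V,
        "left": B,
        # fast-mode pointer: diag of outer(v_fast, b_fast)
        "pointer_fast": V[:, 0] * B[0],
        "amplitude_fast": lambda y: abs(lam_fast * (B[0] @ y)),
        "solution": lambda y0, t: (
            V @ np.array([np.exp(lam_fast * t) * (B[0] @ y0),
                          np.exp(lam_slow * t) * (B[1] @ y0)])),
    }
    return ToySystem(dim=2, labels=("fast", "slow"), S=Smat, rates=rates,
                     rate_gradients=grads, eps=eps, reference=ref)


def linear_two_reaction_relaxation(k1: float, k2: float) -> ToySystem:
    """1-D relaxation dy/dt = -(k1 + k2) y written as two reactions.

    The single mode's TPI is analytically (-k1, -k2) / (k1 + k2).
    """
    S = np.array([[1.0, 1.0]])

    def rates(y):
        return np.array([-k1 * y[0], -k2 * y[0]])

    def grads(y):
        return np.array([[-k1], [-k2]])

    ref = {"tpi": np.array([-k1, -k2]) / (k1 + k2),
           "eigenvalue": -(k1 + k2)}
    return ToySystem(dim=1, labels=("r1", "r2"), S=S, rates=rates,
                     rate_gradients=grads, eps=min(k1, k2) / max(k1, k2),
                     reference=ref)


def enzyme_qssa_system(k1: float = 10.0, k_1: float = 5.0, k2: float = 1.0,
                       E0: float = 0.01, S0: float = 1.0) -> ToySystem:
    """Reversible enzyme kinetics E + S <-> C -> E + P in (S, C) variables.

    With E0 << S0 the complex C is a fast, quasi-steady species: after a
    transient of order 1/(k1(S0 + K_M)) the system collapses onto the
    slow manifold C = E0 S / (K_M + S), K_M = (k_1 + k2)/k1, and the
    fast mode expresses the binding/unbinding partial equilibrium
    (API ~ +-0.5 on the two directions).
    """
    if min(k1, k_1, k2, E0, S0) <= 0:
        raise ValueError("all rate constants and pools must be positive")
    KM = (k_1 + k2) / k1
    # columns: binding, unbinding, catalysis
    Smat = np.array([[-1.0, 1.0, 0.0],
                     [1.0, -1.0, -1.0]])

    def rates(y):
        s, c = y
        return np.array([k1 * s * (E0 - c), k_1 * c, k2 * c])

    def grads(y):
        s, c = y
        return np.array([[k1 * (E0 - c), -k1 * s],
                         [0.0, k_1],
                         [0.0, k2]])

    eps = E0 / (S0 + KM)
    ref = {
        "KM": KM,
        "qss_manifold": lambda s: E0 * s / (KM + s),
        "fast_timescale": 1.0 / (k1 * (S0 + KM)),
        "initial_state": np.array([S0, 0.0]),
    }
    return ToySystem(dim=2, labels=("binding", "unbinding", "catalysis"),
                     S=Smat, rates=rates, rate_gradients=grads, eps=eps,
                     reference=ref)
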