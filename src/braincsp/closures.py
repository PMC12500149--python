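"""Adenine-pool closures and the BOLD observable.

The model tracks ATP only; ADP and AMP follow from conservation of the
total adenine pool A = ATP + ADP + AMP together with adenylate-kinase
equilibrium q_AK * ADP^2 = ATP * AMP.  Eliminating AMP gives a closed
form for ADP(ATP).  Because AMP is slaved to ATP, every flux that
produces or consumes ATP also implicitly moves AMP; the factor
S = (1 - dAMP/dATP)^-1 restores a state-independent stoichiometry by
absorbing that feedback into the rate.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet


def adp_from_atp(ATP_x: float, params: ParameterSet) -> float:
    """ADP concentration (mM) slaved to ATP by the adenylate-kinase closure.

    ADP = ATP/2 * (-q + sqrt(q^2 + 4 q (A/ATP - 1))).

    Raises ``ValueError`` outside the physical domain 0 < ATP <= A.
    """
    A, q = params.A_tot, params.qAK
    if not 0.0 < ATP_x <= A:
        raise ValueError(f"ATP_x={ATP_x} outside the adenine pool (0, {A}]")
    return ATP_x / 2.0 * (-q + math.sqrt(q * q + 4.0 * q * (A / ATP_x - 1.0)))


def amp_from_atp(ATP_x: float, params: ParameterSet) -> float:
    """AMP from pool conservation, A - ATP - ADP(ATP)."""
    return params.A_tot - ATP_x - adp_from_atp(ATP_x, params)


def amp_closure_factor(ATP_x: float, params: ParameterSet) -> float:
    """S(ATP) = (1 - dAMP/dATP)^-1, the stoichiometry-regularisation factor.

    Uses the analytic derivative
    dAMP/dATP = -1 + q/2 - u/2 + q A / (ATP u),
    u = sqrt(q^2 + 4 q (A/ATP - 1)).
    """
    A, q = params.A_tot, params.qAK
    if not 0.0 < ATP_x < A:
        raise ValueError(f"ATP_x={ATP_x} outside (0, A={A})")
    disc = q * q + 4.0 * q * (A / ATP_x - 1.0)
    if disc <= 0.0:
        raise ValueError(f"closure not real at ATP_x={ATP_x}")
    u = math.sqrt(disc)
    damp_datp = -1.0 + q / 2.0 - u / 2.0 + q * A / (ATP_x * u)
    return 1.0 / (1.0 - damp_datp)


def bold_signal(dHb: float | np.ndarray, Vv: float | np.ndarray,
                params: ParameterSet) -> float | np.ndarray:
    """Blood-oxygen-level-dependent signal from deoxyhemoglobin and venous volume.

    BOLD = Vv0 [ (k1+k2)(1 - dHb/dHb0) - (k2+k3)(1 - Vv/Vv0) ], zero at
    baseline and positive when deoxyhemoglobin falls below baseline.
    """
    dHb = np.asarray(dHb, dtype=float)
    Vv = np.asarray(Vv, dtype=float)
    if np.any(dHb <= 0) or np.any(Vv <= 0):
        raise ValueError("dHb and Vv must be positive")
    p = params
    out = p.Vv0 * ((p.k1 + p.k2) * (1.0 - dHb / p.dHb0)
                   - (p.k2 + p.k3) * (1.0 - Vv / p.Vv0))
    return float(out) if out.ndim == 0 else out
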