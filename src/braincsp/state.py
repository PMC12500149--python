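"""State vector layout of the brain energy metabolism model.

The model tracks 29 variables over four compartments: neuronal (``_n``),
astrocytic/glial (``_g``), extracellular (``_e``) and capillary (``_c``).
All variables are concentrations in mM except the venous volume ``Vv``
(dimensionless fraction of tissue volume).  The ordering below is the
public contract used by the stoichiometric matrix, the Jacobians, and
every report.
"""

from __future__ import annotations

import numpy as np

#: Canonical ordering of the 29 state variables.
STATE_NAMES: tuple[str, ...] = (
    "Na_n", "Na_g",
    "GLC_n", "GLC_g",
    "GAP_n", "GAP_g",
    "PEP_n", "PEP_g",
    "PYR_n", "PYR_g",
    "LAC_n", "LAC_g",
    "NADHcyto_n", "NADHcyto_g",
    "NADHmito_n", "NADHmito_g",
    "ATP_n", "ATP_g",
    "PCr_n", "PCr_g",
    "O2_n", "O2_g", "O2_c",
    "GLC_c", "LAC_c",
    "Vv", "dHb",
    "GLC_e", "LAC_e",
)

N_STATES = len(STATE_NAMES)

STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: Published resting-state values (mM; Vv dimensionless).  These are the
#: rounded values of the model's baseline steady state; see
#: :func:`braincsp.simulate.steady_state` for the refined fixed point.
REST_VALUES: dict[str, float] = {
    "Na_n": 8.0, "Na_g": 15.0,
    "GLC_n": 1.2, "GLC_g": 1.19,
    "GAP_n": 0.0046, "GAP_g": 0.0046,
    "PEP_n": 0.015, "PEP_g": 0.015,
    "PYR_n": 0.17, "PYR_g": 0.17,
    "LAC_n": 0.6, "LAC_g": 0.6,
    "NADHcyto_n": 0.006, "NADHcyto_g": 0.1,
    "NADHmito_n": 0.12, "NADHmito_g": 0.12,
    "ATP_n": 2.2, "ATP_g": 2.2,
    "PCr_n": 4.9, "PCr_g": 4.9,
    "O2_n": 0.028, "O2_g": 0.028, "O2_c": 7.0,
    "GLC_c": 4.5, "LAC_c": 0.55,
    "Vv": 0.02, "dHb": 0.058,
    "GLC_e": 2.48, "LAC_e": 0.6,
}


def resting_state() -> np.ndarray:
    """Published resting values as a vector in canonical order."""
    return np.array([REST_VALUES[name] for name in STATE_NAMES])


def validate_state(y: np.ndarray, params) -> None:
    """Raise ``ValueError`` if ``y`` violates the physical invariants.

    Checks non-negativity, the adenine pool bound 0 < ATP_x < A, the
    creatine pool bound 0 <= PCr_x <= C, the NAD pool bound on all NADH
    variables, and Vv > 0.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {y.shape}")
    for i, name in enumerate(STATE_NAMES):
        if y[i] < 0.0:
            raise ValueError(f"negative concentration for {name}: {y[i]}")
    for name in ("ATP_n", "ATP_g"):
        v = y[STATE_INDEX[name]]
        if not 0.0 < v < params.A_tot:
            raise ValueError(f"{name}={v} outside (0, A={params.A_tot})")
    for name in ("PCr_n", "PCr_g"):
        v = y[STATE_INDEX[name]]
        if not 0.0 <= v <= params.C_tot:
            raise ValueError(f"{name}={v} outside [0, C={params.C_tot}]")
    for name in ("NADHcyto_n", "NADHcyto_g", "NADHmito_n", "NADHmito_g"):
        v = y[STATE_INDEX[name]]
        if not 0.0 <= v <= params.N_tot:
            raise ValueError(f"{name}={v} outside [0, N={params.N_tot}]")
    if y[STATE_INDEX["Vv"]] <= 0.0:
        raise ValueError("venous volume Vv must be positive")
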