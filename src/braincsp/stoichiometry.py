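"""Constant stoichiometric matrix of the model.

``S`` is the 29 x 67 matrix such that dy/dt = S @ R(y) with R the vector
of unidirectional rates.  Entries are the signed coefficients of the
governing equations: small integers, the oxidative coefficients 0.6,
3.6, 0.75, 1.75, and the volume-ratio constants c1, c2, r1..r5 that
convert fluxes between compartmental volumes.  The state-dependent
adenine-pool factors S1/S2 live inside the rates of reactions 34-36 and
54-65, never here, so S is state-independent.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet
from .registry import LABEL_INDEX, N_REACTIONS
from .state import N_STATES, STATE_INDEX


def stoichiometric_rows(params: ParameterSet) -> dict[str, dict[str, float]]:
    """Per-state mapping of reaction label to signed coefficient."""
    c1, c2 = params.c1, params.c2
    r1, r2, r3, r4, r5 = params.r1, params.r2, params.r3, params.r4, params.r5
    return {
        "Na_n": {"1": 1, "3": -3, "40": 1},
        "Na_g": {"2": 1, "4": -3, "41": 1},
        "GLC_n": {"5f": 1, "5b": -1, "9": -1},
        "GLC_g": {"6f": 1, "6b": -1, "7f": 1, "7b": -1, "10": -1},
        "GAP_n": {"9": 2, "11": -1},
        "GAP_g": {"10": 2, "12": -1},
        "PEP_n": {"11": 1, "13": -1},
        "PEP_g": {"12": 1, "14": -1},
        "PYR_n": {"13": 1, "15f": -1, "15b": 1, "21": -1},
        "PYR_g": {"14": 1, "16f": -1, "16b": 1, "23": -1},
        "LAC_n": {"15f": 1, "15b": -1, "17f": -1, "17b": 1},
        "LAC_g": {"16f": 1, "16b": -1, "18f": -1, "18b": 1, "19f": -1, "19b": 1},
        "NADHcyto_n": {"11": c1, "15f": -c1, "15b": c1, "25": -c1},
        "NADHcyto_g": {"12": c1, "16f": -c1, "16b": c1, "26": -c1},
        "NADHmito_n": {"21": 4 * c2, "22": -c2, "25": c2},
        "NADHmito_g": {"23": 4 * c2, "24": -c2, "26": c2},
        "ATP_n": {"54": -2, "56": 1, "58": 1, "34": -1, "60": -1,
                  "62": 3.6, "64f": 1, "64b": -1},
        "ATP_g": {"55": -2, "57": 1, "59": 1, "35": -1, "36": 0.75,
                  "61": -1.75, "63": 3.6, "65f": 1, "65b": -1},
        "PCr_n": {"27f": -1, "27b": 1},
        "PCr_g": {"28f": -1, "28b": 1},
        "O2_n": {"29": 1, "22": -0.6},
        "O2_g": {"30": 1, "24": -0.6},
        "O2_c": {"31": 1, "29": -r1, "30": -r2},
        "GLC_c": {"32": 1, "7f": -r2, "7b": r2, "8f": -r3, "8b": r3},
        # Mass balance fixes the + sign on the glia->capillary pair 19.
        "LAC_c": {"33": 1, "19f": r2, "19b": -r2, "20f": r3, "20b": -r3},
        "Vv": {"37": 1},
        "dHb": {"38": 1, "39": -1},
        "GLC_e": {"5f": -r4, "5b": r4, "6f": -r5, "6b": r5, "8f": 1, "8b": -1},
        "LAC_e": {"17f": r4, "17b": -r4, "18f": r5, "18b": -r5, "20f": -1, "20b": 1},
    }


def stoichiometric_matrix(params: ParameterSet) -> np.ndarray:
    """The constant N_states x K matrix in canonical ordering."""
    S = np.zeros((N_STATES, N_REACTIONS))
    for state_name, row in stoichiometric_rows(params).items():
        i = STATE_INDEX[state_name]
        for label, coeff in row.items():
            S[i, LABEL_INDEX[label]] = coeff
    return S
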