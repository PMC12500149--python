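"""Leading-order computational singular perturbation (CSP) decomposition.

At a state y the dynamics dy/dt = g(y) is decomposed into N modes along
the right/left eigenvectors of the Jacobian, ordered fastest first by
|eigenvalue|.  Mode n has timescale tau_n = 1/|lambda_n| and amplitude
f^n = b^n . g.  Fast dissipative modes whose amplitudes have decayed
below an accuracy threshold are "exhausted": they express established
equilibria (e.g. partial equilibria of reversible reactions) rather than
ongoing dynamics, and the system evolves on the manifold f^r ~ 0 driven
by the remaining slow modes, the fastest of which (mode M+1) is the
dominant active mode.

Complex conjugate eigenpairs are represented by their real invariant
2-subspace (real and imaginary parts of one eigenvector,
bi-orthonormalised), so every basis vector, amplitude and diagnostic
index is real; the pair shares one timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ModeDecomposition:
    """Eigen-decomposition of a Jacobian with CSP conventions applied.

    Modes are indexed 0..N-1 fastest to slowest (reports use 1-based
    labels).  ``right[:, n]`` is the column basis vector a_n, ``left[n]``
    the row vector b^n with left @ right = I, ``amplitudes[n]`` the
    non-negative mode amplitude f^n = b^n . g.
    """

    eigenvalues: np.ndarray      # complex, sorted fastest first
    timescales: np.ndarray       # 1/|lambda|, s
    right: np.ndarray            # (N, N) real
    left: np.ndarray             # (N, N) real
    amplitudes: np.ndarray       # (N,) non-negative
    pair_mask: np.ndarray        # True where the mode belongs to a complex pair
    condition: float             # condition number of the eigenbasis

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def eigendecompose(J: np.ndarray, g: np.ndarray,
                   cond_warn: float = 1e10) -> ModeDecomposition:
    """CSP mode decomposition of one state.

    Sorting is a stable key (|lambda| descending, then real part, then
    original index) so near-degenerate magnitudes get reproducible mode
    numbers.  Right vectors are scaled to unit norm; the left matrix is
    the exact matrix inverse, which enforces b^i . a_j = delta_ij to
    machine precision.  Signs of (a_n, b^n) are flipped jointly so every
    amplitude is non-negative.
    """
    J = np.asarray(J, dtype=float)
    g = np.asarray(g, dtype=float)
    N = J.shape[0]
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    lam, V = np.linalg.eig(J)

    order = sorted(range(N), key=lambda i: (-abs(lam[i]), lam[i].real, i))
    lam = lam[order]
    V = V[:, order]

    # Build a real basis: conjugate pairs are adjacent after sorting.
    A = np.empty((N, N))
    pair_mask = np.zeros(N, dtype=bool)
    i = 0
    while i < N:
        if abs(lam[i].imag) > 0 and i + 1 < N and \
                np.isclose(lam[i + 1], np.conj(lam[i])):
            v = V[:, i] if lam[i].imag > 0 else V[:, i + 1]
            A[:, i] = v.real
            A[:, i + 1] = v.imag
            pair_mask[i] = pair_mask[i + 1] = True
            i += 2
        else:
            if abs(lam[i].imag) > 1e-8 * max(abs(lam[i]), 1.0):
                warnings.warn("unpaired complex eigenvalue; using real part "
                              "of its eigenvector")
            A[:, i] = V[:, i].real
            i += 1
    A /= np.linalg.norm(A, axis=0, keepdims=True)

    cond = np.linalg.cond(A)
    if cond > cond_warn:
        warnings.warn(f"near-defective eigenbasis (condition {cond:.2e}); "
                      "CSP diagnostics may be unreliable")
    B = np.linalg.inv(A)

    f = B @ g
    flip = f < 0
    A[:, flip] *= -1.0
    B[flip, :] *= -1.0
    f[flip] *= -1.0

    with np.errstate(divide="ignore"):
        tau = 1.0 / np.abs(lam)
    return ModeDecomposition(eigenvalues=lam, timescales=tau, right=A,
                             left=B, amplitudes=f, pair_mask=pair_mask,
                             condition=cond)


# ---------------------------------------------------------------------------
# Diagnostic indices
# ---------------------------------------------------------------------------

def amplitude_participation_index(decomp: ModeDecomposition, S: np.ndarray,
                                  R: np.ndarray, mode: int) -> np.ndarray:
    """API row for one mode: signed per-reaction share of the amplitude.

    P_k = (b . S_k) R_k / sum_i |(b . S_i) R_i|.  Positive and negative
    entries each sum to 0.5 when the mode expresses a complete
    cancellation (an established equilibrium).
    """
    terms = (decomp.left[mode] @ S) * R
    denom = np.sum(np.abs(terms))
    if denom == 0.0:
        raise ZeroDivisionError(
            f"API undefined for mode {mode}: all projected rates vanish")
    return terms / denom


def timescale_participation_contributions(decomp: ModeDecomposition,
                                          S: np.ndarray,
                                          rate_grads: np.ndarray,
                                          mode: int) -> np.ndarray:
    """Per-reaction contributions c_k = b grad(S_k R_k) a to the eigenvalue.

    Because grad(S_k R_k) = outer(S_k, dR_k/dy), each contribution
    factorises as (b . S_k)(dR_k/dy . a); their sum is b J a, i.e. the
    eigenvalue (its real part for a complex pair in the real basis).
    """
    bS = decomp.left[mode] @ S                # (K,)
    ga = rate_grads @ decomp.right[:, mode]   # (K,)
    return bS * ga


def timescale_participation_index(decomp: ModeDecomposition, S: np.ndarray,
                                  rate_grads: np.ndarray,
                                  mode: int) -> np.ndarray:
    """TPI row: c_k normalised by sum |c_i|; negative entries are
    dissipative (drive toward equilibrium), positive explosive."""
    c = timescale_participation_contributions(decomp, S, rate_grads, mode)
    denom = np.sum(np.abs(c))
    if denom == 0.0:
        raise ZeroDivisionError(f"TPI undefined for mode {mode}")
    return c / denom


def csp_pointer(decomp: ModeDecomposition, mode: int) -> np.ndarray:
    """Pointer row: D_i = a_n[i] * b^n[i], summing to one over species.

    An entry near unity flags the species as quasi-steady-state for this
    mode."""
    return decomp.right[:, mode] * decomp.left[mode]


# ---------------------------------------------------------------------------
# Exhausted-mode criterion
# ---------------------------------------------------------------------------

def count_exhausted_modes(decomp: ModeDecomposition, y: np.ndarray,
                          e_rel: float, e_abs: float) -> int:
    """Number M of exhausted fast modes at this state.

    M is the largest value in [0, N-1] for which the leading-order error
    of freezing the M fastest modes is within tolerance componentwise:

        | tau_{M+1} * sum_{i<=M} a_i f^i |  <  e_rel |y| + e_abs,

    required to hold for every M' <= M as well: exhaustion accumulates
    mode by mode, so the count stops at the first mode whose inclusion
    violates the accuracy bound (accidental cancellations inside the
    partial sum cannot re-admit a larger M past a failing one).

    At an exact steady state every amplitude vanishes and M = N-1.
    """
    if e_rel <= 0 or e_abs <= 0:
        raise ValueError("tolerances must be positive")
    y = np.asarray(y, dtype=float)
    N = decomp.n_modes
    tol = e_rel * np.abs(y) + e_abs
    contrib = decomp.right * decomp.amplitudes[None, :]   # a_i f^i columns
    partial = np.cumsum(contrib, axis=1)                  # sum over i<=M
    best = 0
    for M in range(1, N):
        err = decomp.timescales[M] * np.abs(partial[:, M - 1])
        if not np.all(err < tol):
            break
        best = M
    return best
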