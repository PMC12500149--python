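"""CSP mode decomposition and diagnostic indices."""

import numpy as np
import pytest

from braincsp import (amplitude_participation_index, count_exhausted_modes,
                      csp_pointer, eigendecompose,
                      timescale_participation_index)
from braincsp.csp import timescale_participation_contributions
from braincsp.segmentation import decompose_at


class TestEigendecompose:
    def test_diagonal_system(self):
        J = np.diag([-100.0, -1.0])
        g = np.array([0.3, -0.7])
        d = eigendecompose(J, g)
        assert np.allclose(d.timescales, [0.01, 1.0])
        # unit basis vectors up to sign
        assert np.allclose(np.abs(d.right), np.eye(2))
        assert np.allclose(np.abs(d.left), np.eye(2))
        assert np.all(d.amplitudes >= 0)

    def test_known_2x2_eigenpairs(self):
        """Nondiagonal system with hand-derived eigenstructure:
        J = [[-2, 1], [0, -5]] has eigenvalues -2, -5 with right
        eigenvectors (1, 0) and (1, -3)/sqrt(10)."""
        J = np.array([[-2.0, 1.0], [0.0, -5.0]])
        d = eigendecompose(J, np.array([1.0, 1.0]))
        assert np.allclose(sorted(d.eigenvalues.real), [-5.0, -2.0])
        # fastest first
        assert d.eigenvalues[0].real == pytest.approx(-5.0)
        v_fast = d.right[:, 0] / np.linalg.norm(d.right[:, 0])
        assert np.allclose(np.abs(v_fast), [1 / np.sqrt(10), 3 / np.sqrt(10)])

    def test_steady_state_amplitudes_vanish(self):
        J = np.array([[-3.0, 0.5], [0.2, -1.0]])
        d = eigendecompose(J, np.zeros(2))
        assert np.allclose(d.amplitudes, 0.0)
        assert count_exhausted_modes(d, np.array([1.0, 1.0]), 1e-6, 1e-12) == 1

    def test_sort_is_deterministic(self, model, baseline):
        J = model.jacobian(baseline, 450.0)
        g = model.vector_field(baseline, 450.0)
        d1 = eigendecompose(J, g)
        d2 = eigendecompose(J, g)
        assert np.array_equal(d1.eigenvalues, d2.eigenvalues)
        assert np.array_equal(d1.right, d2.right)

    def test_nonfinite_jacobian_rejected(self):
        J = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            eigendecompose(J, np.zeros(2))


class TestIdentitiesOnBrainModel:
    """Exact algebraic identities, checked along the scenario."""

    TIMES = [25.0, 500.0, 850.0, 950.0, 1300.0, 2000.0, 6500.0]

    def test_biorthonormality(self, trajectory):
        for t in self.TIMES:
            _, d = decompose_at(trajectory, t)
            resid = d.left @ d.right - np.eye(29)
            assert np.max(np.abs(resid)) < 1e-8

    def test_basis_reconstructs_vector_field(self, trajectory):
        for t in self.TIMES:
            y, d = decompose_at(trajectory, t)
            g = trajectory.model.vector_field(y, t)
            recon = d.right @ d.amplitudes
            assert np.allclose(recon, g, rtol=1e-6, atol=1e-12)

    def test_index_normalisations(self, trajectory):
        model = trajectory.model
        for t in self.TIMES:
            y, d = decompose_at(trajectory, t)
            R = model.rates(y, t)
            grads = model.rate_gradients(y, t)
            for mode in (0, 10, d.n_modes - 2):
                api = amplitude_participation_index(d, model.S, R, mode)
                assert np.sum(np.abs(api)) == pytest.approx(1.0, abs=1e-8)
                tpi = timescale_participation_index(d, model.S, grads, mode)
                assert np.sum(np.abs(tpi)) == pytest.approx(1.0, abs=1e-8)
                po = csp_pointer(d, mode)
                assert np.sum(po) == pytest.approx(1.0, abs=1e-8)

    def test_tpi_contributions_sum_to_eigenvalue(self, trajectory,
                                                 random_states):
        """sum_k c_k^n = lambda_n (real part for a conjugate pair in the
        real invariant basis) at perturbed states of the model."""
        model = trajectory.model
        for y in random_states(20):
            g = model.vector_field(y, 450.0)
            J = model.jacobian(y, 450.0)
            d = eigendecompose(J, g)
            grads = model.rate_gradients(y, 450.0)
            for mode in (0, 5, 17, 28):
                c = timescale_participation_contributions(d, model.S, grads,
                                                          mode)
                assert np.sum(c) == pytest.approx(d.eigenvalues[mode].real,
                                                  rel=1e-8, abs=1e-12)


class TestExhaustedModeCriterion:
    def test_rejects_nonpositive_tolerances(self):
        d = eigendecompose(np.diag([-2.0, -1.0]), np.ones(2))
        with pytest.raises(ValueError):
            count_exhausted_modes(d, np.ones(2), 0.0, 1e-6)

    def test_m_zero_when_fastest_mode_active(self):
        """Right after a perturbation even the fastest mode carries a
        large amplitude and no mode can be frozen."""
        J = np.diag([-100.0, -1.0])
        g = np.array([50.0, 0.1])    # fast mode far from its manifold
        d = eigendecompose(J, g)
        assert count_exhausted_modes(d, np.array([1.0, 1.0]),
                                     1e-3, 1e-9) == 0
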