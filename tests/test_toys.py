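"""Toy multiscale systems: the CSP engine against closed forms."""

import numpy as np
import pytest

from braincsp import (count_exhausted_modes, csp_pointer, eigendecompose,
                      enzyme_qssa_system, linear_two_reaction_relaxation,
                      linear_two_scale_system,
                      timescale_participation_index)
from braincsp.csp import amplitude_participation_index


class TestLinearTwoScale:
    def test_rejects_eps_out_of_range(self):
        with pytest.raises(ValueError):
            linear_two_scale_system(1.5)

    def test_eigenstructure_matches_construction(self):
        toy = linear_two_scale_system(0.01)
        y = np.array([0.4, 1.3])
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        assert np.allclose(sorted(d.eigenvalues.real), [-100.0, -1.0])
        assert np.allclose(d.timescales, toy.reference["timescales"])

    def test_fast_pointer_is_unit_vector_when_orthogonal(self):
        toy = linear_two_scale_system(0.01, angle=np.pi / 2)
        y = np.array([1.0, 1.0])
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        assert np.allclose(csp_pointer(d, 0), toy.reference["pointer_fast"],
                           atol=1e-12)
        assert np.allclose(csp_pointer(d, 0), [1.0, 0.0], atol=1e-12)

    def test_tpi_isolates_one_reaction_per_mode(self):
        """Each toy 'reaction' generates exactly one eigendirection, so
        the TPI of mode n is +-100 % on reaction n."""
        toy = linear_two_scale_system(0.05, angle=1.0)
        y = np.array([0.7, -0.2])
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        grads = toy.rate_gradients(y)
        tpi_fast = timescale_participation_index(d, toy.S, grads, 0)
        tpi_slow = timescale_participation_index(d, toy.S, grads, 1)
        assert np.allclose(np.abs(tpi_fast), [1.0, 0.0], atol=1e-12)
        assert np.allclose(np.abs(tpi_slow), [0.0, 1.0], atol=1e-12)

    def test_two_reaction_relaxation_tpi(self):
        toy = linear_two_reaction_relaxation(k1=3.0, k2=1.0)
        y = np.array([0.8])
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        tpi = timescale_participation_index(d, toy.S, toy.rate_gradients(y), 0)
        assert np.allclose(tpi, toy.reference["tpi"])   # (-k1,-k2)/(k1+k2)

    def test_exhaustion_time_scales_with_fast_timescale(self):
        """M steps 0 -> 1 once the fast amplitude has decayed:
        t* ~ eps * ln(|lambda_f| tau_slow / tol)."""
        eps, e_rel, e_abs = 0.01, 1e-3, 1e-9
        toy = linear_two_scale_system(eps)
        y0 = np.array([1.0, 1.0])

        def M_at(t):
            y = toy.reference["solution"](y0, t)
            d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
            return count_exhausted_modes(d, y, e_rel, e_abs)

        t_star = eps * np.log(1.0 / (eps * e_rel))   # amplitude/tolerance
        assert M_at(0.2 * t_star) == 0
        assert M_at(3.0 * t_star) == 1

    def test_leading_order_reduction_error_decays_with_gap(self):
        """Freezing the fast mode leaves an off-manifold error that
        shrinks proportionally to the timescale-gap ratio eps."""
        errors = []
        for eps in (0.1, 0.01, 0.001):
            toy = linear_two_scale_system(eps, angle=np.pi / 3)
            y0 = np.array([1.0, 1.0])
            t = 5.0 * eps * np.log(1 / eps)   # past the fast transient
            y = toy.reference["solution"](y0, t)
            d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
            # off-manifold displacement reconstructed from the fast mode
            err = np.linalg.norm(d.timescales[0] * d.right[:, 0]
                                 * d.amplitudes[0])
            errors.append(err / np.linalg.norm(y))
        assert errors[0] > errors[1] > errors[2]
        # decay at least linear in eps
        assert errors[2] < errors[0] * (0.001 / 0.1) * 10


class TestEnzymeQSSA:
    def test_rejects_nonpositive_constants(self):
        with pytest.raises(ValueError):
            enzyme_qssa_system(k1=-1.0)

    def test_fast_api_is_binding_unbinding_partial_equilibrium(self):
        """After the transient the fast mode expresses the partial
        equilibrium of the binding/unbinding pair: API ~ +0.5 / -0.5,
        positive and negative halves each summing to ~0.5."""
        toy = enzyme_qssa_system(k1=100.0, k_1=50.0, k2=1.0, E0=0.001, S0=1.0)
        t = np.linspace(0.0, 50 * toy.reference["fast_timescale"], 50)
        y = toy.solve(toy.reference["initial_state"] + [0, 1e-6], t)[-1]
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        api = amplitude_participation_index(d, toy.S, toy.rates(y), 0)
        assert api[np.argmax(np.abs(api))] * api[1] < 0  # opposite signs
        assert abs(api[0]) == pytest.approx(0.5, abs=0.02)   # binding
        assert abs(api[1]) == pytest.approx(0.5, abs=0.02)   # unbinding
        assert abs(api[2]) < 0.04                            # catalysis

    def test_fast_pointer_concentrates_on_complex_as_gap_grows(self):
        vals = []
        for E0 in (0.1, 0.01, 0.001):
            toy = enzyme_qssa_system(E0=E0)
            s = 0.8 * 1.0
            y = np.array([s, 0.9 * toy.reference["qss_manifold"](s)])
            d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
            vals.append(csp_pointer(d, 0)[1])   # complex entry
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] == pytest.approx(1.0, abs=0.01)

    def test_dynamics_tracks_qss_manifold_within_order_eps(self):
        toy = enzyme_qssa_system(k1=10.0, k_1=5.0, k2=1.0, E0=0.01, S0=1.0)
        tau_f = toy.reference["fast_timescale"]
        t = np.linspace(0.0, 2.0, 200)
        Y = toy.solve(toy.reference["initial_state"], t)
        post = t > 20 * tau_f
        c_exact = Y[post, 1]
        c_qss = toy.reference["qss_manifold"](Y[post, 0])
        rel = np.max(np.abs(c_exact - c_qss) / np.abs(c_exact))
        assert rel < 5 * toy.eps
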