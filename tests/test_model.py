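"""Registry, stoichiometry and rate laws of the metabolic model."""

import numpy as np
import pytest

from braincsp import LABELS, REACTIONS, ScenarioProtocol, compute_rates
from braincsp.registry import LABEL_INDEX, reaction, reversible_partner
from braincsp.state import STATE_INDEX, STATE_NAMES
from braincsp.stoichiometry import stoichiometric_rows


def _direct_rhs(Rd: dict[str, float], p) -> dict[str, float]:
    """The governing equations written out literally, one per variable,
    as an oracle independent of the stoichiometric-matrix bookkeeping."""
    c1, c2 = p.c1, p.c2
    r1, r2, r3, r4, r5 = p.r1, p.r2, p.r3, p.r4, p.r5
    return {
        "Na_n": Rd["1"] - 3 * Rd["3"] + Rd["40"],
        "Na_g": Rd["2"] - 3 * Rd["4"] + Rd["41"],
        "GLC_n": (Rd["5f"] - Rd["5b"]) - Rd["9"],
        "GLC_g": (Rd["6f"] - Rd["6b"]) + (Rd["7f"] - Rd["7b"]) - Rd["10"],
        "GAP_n": 2 * Rd["9"] - Rd["11"],
        "GAP_g": 2 * Rd["10"] - Rd["12"],
        "PEP_n": Rd["11"] - Rd["13"],
        "PEP_g": Rd["12"] - Rd["14"],
        "PYR_n": Rd["13"] - (Rd["15f"] - Rd["15b"]) - Rd["21"],
        "PYR_g": Rd["14"] - (Rd["16f"] - Rd["16b"]) - Rd["23"],
        "LAC_n": (Rd["15f"] - Rd["15b"]) - (Rd["17f"] - Rd["17b"]),
        "LAC_g": (Rd["16f"] - Rd["16b"]) - (Rd["18f"] - Rd["18b"])
                 - (Rd["19f"] - Rd["19b"]),
        "NADHcyto_n": c1 * (Rd["11"] - (Rd["15f"] - Rd["15b"]) - Rd["25"]),
        "NADHcyto_g": c1 * (Rd["12"] - (Rd["16f"] - Rd["16b"]) - Rd["26"]),
        "NADHmito_n": c2 * (4 * Rd["21"] - Rd["22"] + Rd["25"]),
        "NADHmito_g": c2 * (4 * Rd["23"] - Rd["24"] + Rd["26"]),
        "ATP_n": -2 * Rd["54"] + Rd["56"] + Rd["58"] - Rd["34"] - Rd["60"]
                 + 3.6 * Rd["62"] + Rd["64f"] - Rd["64b"],
        "ATP_g": -2 * Rd["55"] + Rd["57"] + Rd["59"] - Rd["35"]
                 + 0.75 * Rd["36"] - 1.75 * Rd["61"] + 3.6 * Rd["63"]
                 + Rd["65f"] - Rd["65b"],
        "PCr_n": -(Rd["27f"] - Rd["27b"]),
        "PCr_g": -(Rd["28f"] - Rd["28b"]),
        "O2_n": Rd["29"] - 0.6 * Rd["22"],
        "O2_g": Rd["30"] - 0.6 * Rd["24"],
        "O2_c": Rd["31"] - r1 * Rd["29"] - r2 * Rd["30"],
        "GLC_c": Rd["32"] - r2 * (Rd["7f"] - Rd["7b"])
                 - r3 * (Rd["8f"] - Rd["8b"]),
        "LAC_c": Rd["33"] + r2 * (Rd["19f"] - Rd["19b"])
                 + r3 * (Rd["20f"] - Rd["20b"]),
        "Vv": Rd["37"],
        "dHb": Rd["38"] - Rd["39"],
        "GLC_e": -r4 * (Rd["5f"] - Rd["5b"]) - r5 * (Rd["6f"] - Rd["6b"])
                 + (Rd["8f"] - Rd["8b"]),
        "LAC_e": r4 * (Rd["17f"] - Rd["17b"]) + r5 * (Rd["18f"] - Rd["18b"])
                 - (Rd["20f"] - Rd["20b"]),
    }


class TestRegistry:
    def test_labels_unique_and_complete(self):
        assert len(LABELS) == 67 == len(set(LABELS))
        used = {lab for row in stoichiometric_rows(
            __import__("braincsp").ParameterSet()).values() for lab in row}
        assert used == set(LABELS)

    def test_reversible_pairs_link_exactly_two(self):
        for r in REACTIONS:
            partner = reversible_partner(r.label)
            if r.direction:
                assert partner is not None
                assert reversible_partner(partner) == r.label
            else:
                assert partner is None

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError, match="42"):
            reaction("42")

    def test_ordering_by_number_forward_first(self):
        nums = [r.number for r in REACTIONS]
        assert nums == sorted(nums)
        for a, b in zip(REACTIONS[:-1], REACTIONS[1:]):
            if a.number == b.number:
                assert (a.direction, b.direction) == ("f", "b")


class TestVectorField:
    def test_matrix_times_rates_matches_direct_equations(self, model,
                                                         random_states):
        """S @ R reproduces every governing equation term-by-term at 100
        random physiological states."""
        for y in random_states(100):
            R = model.rates(y, t=450.0)
            Rd = dict(zip(LABELS, R))
            g = model.vector_field(y, t=450.0)
            direct = _direct_rhs(Rd, model.params)
            for i, name in enumerate(STATE_NAMES):
                assert g[i] == pytest.approx(direct[name], rel=1e-12,
                                             abs=1e-15), name

    def test_phosphocreatine_row_is_net_creatine_kinase(self, model, baseline):
        R = model.rates(baseline, 0.0)
        g = model.vector_field(baseline, 0.0)
        i = STATE_INDEX["PCr_n"]
        net = R[LABEL_INDEX["27f"]] - R[LABEL_INDEX["27b"]]
        assert g[i] == pytest.approx(-net, rel=0, abs=0)

    def test_capillary_lactate_perturbation_sparsity(self, model, baseline):
        """Perturbing LAC_c only moves the lactate rows that reference
        the g->c, e->c and capillary-flow rates."""
        y2 = baseline.copy()
        y2[STATE_INDEX["LAC_c"]] *= 1.05
        dg = model.vector_field(y2, 0.0) - model.vector_field(baseline, 0.0)
        affected = {i for i in range(29) if abs(dg[i]) > 1e-14}
        expected = {STATE_INDEX[n] for n in ("LAC_c", "LAC_g", "LAC_e")}
        assert affected == expected


class TestRates:
    def test_stimulation_window(self, params):
        proto = ScenarioProtocol()
        y = np.full(29, 0.5)
        y[STATE_INDEX["ATP_n"]] = y[STATE_INDEX["ATP_g"]] = 2.0
        inside = compute_rates(y, params, 450.0, proto)
        after = compute_rates(y, params, 901.0, proto)
        assert inside[LABEL_INDEX["40"]] == pytest.approx(0.15290)
        assert inside[LABEL_INDEX["41"]] == pytest.approx(0.059823)
        assert after[LABEL_INDEX["40"]] == after[LABEL_INDEX["41"]] == 0.0

    def test_hexokinase_vanishes_without_glucose(self, model, baseline):
        y = baseline.copy()
        y[STATE_INDEX["GLC_n"]] = 0.0
        R = model.rates(y, 0.0)
        assert R[LABEL_INDEX["9"]] == 0.0

    def test_baseline_is_near_equilibrium(self, params, baseline):
        """At the refined resting state, under baseline flow and no
        stimulation, every reversible pair's net rate balances the rest
        of its row: the vector-field residual is at Newton tolerance."""
        from braincsp import BrainModel, null_protocol
        g = BrainModel(params, null_protocol()).vector_field(baseline, 0.0)
        assert np.max(np.abs(g)) < 1e-9

    def test_unidirectional_rates_nonnegative(self, model, random_states):
        pair_labels = [r.label for r in REACTIONS if r.direction]
        idx = [LABEL_INDEX[lab] for lab in pair_labels]
        for y in random_states(50):
            R = model.rates(y, 450.0)
            assert np.all(R[idx] >= 0)

    def test_negative_concentration_rejected(self, model, baseline):
        y = baseline.copy()
        y[0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            model.rates(y, 0.0)
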