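"""Dominant-mode tables, equilibria graphs, and their serialisation."""

import json

import numpy as np
import pytest

from braincsp import dominant_mode_report, equilibria_graph, write_outputs
from braincsp.registry import LABELS
from braincsp.reporting import TPI_FILTER
from braincsp.segmentation import Period


@pytest.fixture(scope="module")
def p3_report(period_table, trajectory):
    p850 = next(p for p in period_table if p.t_start <= 850.0 <= p.t_end)
    return dominant_mode_report(p850, trajectory)


class TestDominantModeReport:
    def test_filter_threshold_semantics(self):
        """A synthetic index vector {0.50, 0.47, 0.03} keeps exactly the
        entries >= 0.03 under the published 3 % convention."""
        vec = np.array([0.50, 0.47, 0.03, 0.029, 0.001])
        kept = vec[np.abs(vec) >= TPI_FILTER]
        assert list(kept) == [0.50, 0.47, 0.03]

    def test_reactions_sorted_descending_and_filtered(self, p3_report):
        mags = [abs(v) for _, v in p3_report.reactions]
        assert mags == sorted(mags, reverse=True)
        assert all(m >= 3.0 for m in mags)     # percent scale

    def test_late_activation_mode_is_neuronal_phosphocreatine(self, p3_report):
        """In the last activation period the dominant mode attaches to
        PCr_n and the neuronal creatine kinase carries the largest TPI."""
        assert p3_report.species[0][0] == "PCr_n"
        assert p3_report.species[0][1] == pytest.approx(0.999, abs=0.05)
        assert p3_report.reactions[0][0] == "27f"
        assert p3_report.character == "dissipative"

    def test_single_reaction_mode_reports_full_tpi(self):
        """A mode generated by one reaction has TPI = +-100 %."""
        from braincsp import (eigendecompose, linear_two_scale_system,
                              timescale_participation_index)
        toy = linear_two_scale_system(0.01)
        y = np.array([1.0, 1.0])
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        tpi = 100 * timescale_participation_index(
            d, toy.S, toy.rate_gradients(y), 0)
        assert sorted(np.abs(tpi)) == pytest.approx([0.0, 100.0], abs=1e-9)

    def test_representative_time_outside_period_rejected(self, trajectory):
        bad = Period(label="PX", t_start=100.0, t_end=200.0, M=17,
                     epoch="activation", representative_time=500.0)
        with pytest.raises(ValueError):
            dominant_mode_report(bad, trajectory)

    def test_normalisation_reverifies_after_filtering(self, period_table,
                                                      trajectory):
        """The full (pre-filter) TPI row still sums to 100 % in absolute
        value; the filtered rows are a subset of it."""
        from braincsp.csp import timescale_participation_index
        from braincsp.segmentation import decompose_at
        p = next(p for p in period_table if p.t_start <= 500.0 <= p.t_end)
        rep = dominant_mode_report(p, trajectory)
        y, d = decompose_at(trajectory, p.representative_time)
        grads = trajectory.model.rate_gradients(y, p.representative_time)
        tpi = 100 * timescale_participation_index(d, trajectory.model.S,
                                                  grads, p.M)
        assert np.sum(np.abs(tpi)) == pytest.approx(100.0, abs=1e-6)
        full = dict(zip(LABELS, tpi))
        for lab, val in rep.reactions:
            assert full[lab] == pytest.approx(val, abs=1e-9)


class TestEquilibriaGraph:
    def test_partial_equilibrium_pair_is_strong(self):
        """A reversible pair at partial equilibrium carries ~+-0.5 API in
        the fast mode and is classified strong in both directions."""
        from braincsp import enzyme_qssa_system
        toy = enzyme_qssa_system(k1=100.0, k_1=50.0, k2=1.0, E0=0.001, S0=1.0)
        t = np.linspace(0.0, 0.5, 50)
        y = toy.solve(toy.reference["initial_state"] + [0, 1e-6], t)[-1]
        from braincsp import amplitude_participation_index, eigendecompose
        d = eigendecompose(toy.jacobian(y), toy.vector_field(y))
        api = amplitude_participation_index(d, toy.S, toy.rates(y), 0)
        assert abs(api[0]) > 0.09 and abs(api[1]) > 0.09

    def test_strong_and_weak_sets_disjoint(self, period_table, trajectory):
        p = next(p for p in period_table if p.t_start <= 500.0 <= p.t_end)
        g = equilibria_graph(p, trajectory)
        assert set(g.strong).isdisjoint(g.weak)
        assert g.n_exhausted == p.M

    def test_zero_exhausted_modes_warns_and_returns_empty(self, trajectory):
        p0 = Period(label="P0", t_start=0.0, t_end=10.0, M=0,
                    epoch="activation", representative_time=5.0)
        with pytest.warns(UserWarning, match="no exhausted"):
            g = equilibria_graph(p0, trajectory)
        assert not g.strong and not g.weak and not g.species


class TestWriteOutputs:
    def test_round_trip_and_determinism(self, tmp_path, p3_report,
                                        period_table, trajectory):
        p = next(p for p in period_table if p.t_start <= 850.0 <= p.t_end)
        g = equilibria_graph(p, trajectory)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs([p3_report], [g], d1)
        write_outputs([p3_report], [g], d2)
        for name in ("dominant_modes.csv", "dominant_modes.json",
                     "equilibria.json", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        payload = json.loads((d1 / "dominant_modes.json").read_text())
        assert payload[0]["period"] == p3_report.period
        assert payload[0]["species"][0][0] == "PCr_n"

    def test_empty_reports_manifest_only(self, tmp_path):
        written = write_outputs([], [], tmp_path / "empty")
        assert [p.name for p in written] == ["manifest.json"]
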