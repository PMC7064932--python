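"""Tests for the steady-state two-phase network flow solver."""

import math

import numpy as np
import pytest

from capnet import units
from capnet.netgen import ArteriolarTree, VesselSegment
from capnet.flow_solver import BoundaryConditions, solve, summarize_terminals
from capnet.rheology import DEFAULT_RHEOLOGY, rbc_split, relative_viscosity, tube_hct


def _tree_from_segments(segs):
    return ArteriolarTree(segments={s.id: s for s in segs}, root_id=0)


def _single_segment(D=40.0, L=400.0):
    return _tree_from_segments([VesselSegment(id=0, diameter=D, length=L)])


def _two_level_tree():
    """Root plus two bifurcations: 7 segments, 4 terminals."""
    segs = [
        VesselSegment(id=0, diameter=30.0, length=300.0, daughter_ids=(1, 2)),
        VesselSegment(id=1, diameter=24.0, length=240.0, parent_id=0, daughter_ids=(3, 4)),
        VesselSegment(id=2, diameter=21.0, length=210.0, parent_id=0, daughter_ids=(5, 6)),
        VesselSegment(id=3, diameter=18.0, length=180.0, parent_id=1),
        VesselSegment(id=4, diameter=16.0, length=160.0, parent_id=1),
        VesselSegment(id=5, diameter=16.0, length=160.0, parent_id=2),
        VesselSegment(id=6, diameter=14.0, length=140.0, parent_id=2),
    ]
    return _tree_from_segments(segs)


class TestSingleSegment:
    def test_poiseuille_closed_form(self):
        D, L, dp, hd = 40.0, 400.0, 12.0, 0.42
        state = solve(_single_segment(D, L), BoundaryConditions(dp, hd))
        eta = relative_viscosity(D, hd) * DEFAULT_RHEOLOGY.plasma_viscosity_mPa_s * 1e-3
        q_m3 = (math.pi * (D * 1e-6) ** 4 * dp * units.MMHG_TO_PA) / (128 * eta * L * 1e-6)
        assert state.inlet_blood_flow_nl_s == pytest.approx(q_m3 * 1e12, rel=1e-9)
        assert state.table.loc[0, "discharge_hct"] == hd
        assert state.table.loc[0, "tube_hct"] == pytest.approx(tube_hct(D, hd))


class TestSymmetricTree:
    def test_terminals_identical(self, balanced_tree):
        state = solve(balanced_tree, BoundaryConditions(12.0, 0.42))
        term = state.terminals()
        assert np.ptp(term["blood_flow_nl_s"].to_numpy()) < 1e-12 * term["blood_flow_nl_s"].mean()
        np.testing.assert_allclose(term["discharge_hct"], 0.42, atol=1e-12)
        summary = summarize_terminals(state)
        assert summary["rbc_flow_nl_s"]["q3"] == pytest.approx(
            summary["rbc_flow_nl_s"]["q1"], rel=1e-12)


class TestConservationAndScaling:
    def test_blood_and_rbc_conserved_at_every_node(self, small_tree, small_state):
        tab = small_state.table
        for i, s in small_tree.segments.items():
            if s.daughter_ids is None:
                continue
            ia, ib = s.daughter_ids
            qp = tab.loc[i, "blood_flow_nl_s"]
            assert abs(tab.loc[ia, "blood_flow_nl_s"] + tab.loc[ib, "blood_flow_nl_s"]
                       - qp) < 1e-8 * qp
            rp = tab.loc[i, "rbc_flow_nl_s"]
            assert abs(tab.loc[ia, "rbc_flow_nl_s"] + tab.loc[ib, "rbc_flow_nl_s"]
                       - rp) < 1e-8 * rp

    def test_rbc_flux_weighted_terminal_hct_equals_inlet(self, small_state):
        term = small_state.terminals()
        hd = term["rbc_flow_nl_s"].sum() / term["blood_flow_nl_s"].sum()
        assert hd == pytest.approx(0.42, abs=1e-6)

    def test_tube_below_discharge_everywhere(self, small_state):
        tab = small_state.table
        assert (tab["tube_hct"] <= tab["discharge_hct"] + 1e-12).all()

    def test_pressure_scaling_is_exactly_linear(self, small_tree, small_state):
        scaled = solve(small_tree, BoundaryConditions(24.0, 0.42))
        np.testing.assert_allclose(scaled.table["blood_flow_nl_s"],
                                   2.0 * small_state.table["blood_flow_nl_s"], rtol=1e-9)
        np.testing.assert_allclose(scaled.table["discharge_hct"],
                                   small_state.table["discharge_hct"], atol=1e-9)
        np.testing.assert_allclose(scaled.table["tube_hct"],
                                   small_state.table["tube_hct"], atol=1e-9)


class TestOracleEquivalence:
    def test_matches_brute_force_fixed_point_on_seven_segments(self):
        """Independent fixed-point iteration (no tree collapse) as oracle."""
        tree = _two_level_tree()
        bc = BoundaryConditions(10.0, 0.42)
        state = solve(tree, bc)

        # oracle: iterate resistances -> solve the 2x2 parallel system by
        # explicit conductance sums -> propagate hematocrit; no damping
        mu_p = DEFAULT_RHEOLOGY.plasma_viscosity_mPa_s * 1e-3
        ids = sorted(tree.segments)
        D = {i: tree.segments[i].diameter for i in ids}
        L = {i: tree.segments[i].length for i in ids}
        hd = {i: 0.42 for i in ids}
        dp = 10.0 * units.MMHG_TO_PA
        for _ in range(400):
            R = {i: 128 * relative_viscosity(D[i], hd[i]) * mu_p * (L[i] * 1e-6)
                 / (math.pi * (D[i] * 1e-6) ** 4) for i in ids}
            # conductances of the two middle subtrees then the root
            g1 = 1.0 / (R[1] + 1.0 / (1.0 / R[3] + 1.0 / R[4]))
            g2 = 1.0 / (R[2] + 1.0 / (1.0 / R[5] + 1.0 / R[6]))
            q = {0: dp / (R[0] + 1.0 / (g1 + g2))}
            q[1] = q[0] * g1 / (g1 + g2)
            q[2] = q[0] * g2 / (g1 + g2)
            for p, (a, b) in ((1, (3, 4)), (2, (5, 6))):
                ga, gb = 1.0 / R[a], 1.0 / R[b]
                q[a] = q[p] * ga / (ga + gb)
                q[b] = q[p] * gb / (ga + gb)
            new_hd = {0: 0.42}
            for p, (a, b) in ((0, (1, 2)), (1, (3, 4)), (2, (5, 6))):
                fqe = rbc_split(q[a] / q[p], D[p], D[a], D[b], new_hd[p])
                new_hd[a] = fqe * new_hd[p] * q[p] / q[a]
                new_hd[b] = (1 - fqe) * new_hd[p] * q[p] / q[b]
            hd = {i: 0.5 * (hd[i] + new_hd[i]) for i in ids}
        for i in ids:
            assert state.table.loc[i, "blood_flow_nl_s"] == pytest.approx(
                q[i] * 1e12, rel=1e-6)
            assert state.table.loc[i, "discharge_hct"] == pytest.approx(hd[i], abs=1e-6)


class TestDiagnostics:
    def test_reports_convergence_metadata(self, small_state):
        assert small_state.iterations >= 1
        assert small_state.residual < 1e-8

    def test_invalid_bc_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(-1.0, 0.42)
        with pytest.raises(ValueError):
            BoundaryConditions(12.0, 1.2)
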