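"""Tests for microbubble transport, residency and the capillary census."""

import numpy as np
import pytest

from capnet.flow_solver import BoundaryConditions, solve
from capnet.microbubble import (CapillaryBedParams, MicrobubbleParams,
                                capillary_census, inlet_mb_rate, mb_split, propagate)
from capnet.rheology import rbc_split


class TestInletRate:
    def test_bed_demand_arithmetic(self):
        # 2.2e4 capillaries x 12 RBC/s, one bubble per 6000 RBCs
        bed = CapillaryBedParams()
        assert bed.n_capillaries * bed.reference_supply_rate_rbc_s == 2.64e5
        assert inlet_mb_rate(bed) == pytest.approx(44.0)

    def test_linear_in_bubble_ratio(self):
        bed = CapillaryBedParams()
        half = MicrobubbleParams(mb_to_rbc_ratio=1.0 / 12000.0)
        assert inlet_mb_rate(bed, half) == pytest.approx(inlet_mb_rate(bed) / 2)

    def test_scales_with_inlet_rbc_flow(self, small_tree, small_state):
        hi = solve(small_tree, BoundaryConditions(24.0, 0.42))
        bed = CapillaryBedParams()
        scaled = inlet_mb_rate(bed, state=hi, reference_state=small_state)
        assert scaled == pytest.approx(2 * inlet_mb_rate(bed), rel=1e-9)


class TestMbSplit:
    def test_equals_rbc_law_above_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            df = rng.uniform(30.001, 75)
            da, db = 0.8 * df, rng.uniform(0.5, 1.0) * 0.8 * df
            fqb, hd = rng.uniform(0, 1), rng.uniform(0.1, 0.6)
            assert mb_split(fqb, df, da, db, hd) == rbc_split(fqb, df, da, db, hd)

    def test_symmetric_half_split_at_any_diameter(self):
        for df in (8.0, 15.0, 29.0, 50.0):
            assert mb_split(0.5, df, 0.8 * df, 0.8 * df, 0.42) == 0.5

    def test_small_vessel_cutoff_exceeds_rbc_cutoff(self):
        # a fractional flow that still carries RBCs but no bubbles
        df, hd = 15.0, 0.42
        x0_rbc = 0.964 * (1 - hd) / df
        fqb = 0.35                      # well above the RBC cutoff
        assert rbc_split(fqb, df, 12.0, 12.0, hd) > 0.0
        assert mb_split(fqb, df, 12.0, 12.0, hd) == 0.0
        assert fqb > x0_rbc

    def test_complementary_daughters_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            df = rng.uniform(8, 60)
            da, db = 0.8 * df, rng.uniform(0.5, 1.0) * 0.8 * df
            fqb, hd = rng.uniform(0, 1), rng.uniform(0.1, 0.6)
            s = mb_split(fqb, df, da, db, hd) + mb_split(1 - fqb, df, db, da, hd)
            assert s == pytest.approx(1.0, abs=1e-12)


class TestPropagate:
    def test_flux_conserved_at_every_node(self, small_tree, small_state):
        mb = propagate(small_state, small_tree, 44.0)
        tab = mb.table
        for i, s in small_tree.segments.items():
            if s.daughter_ids is None:
                continue
            fa = tab.loc[s.daughter_ids[0], "mb_flux_per_s"]
            fb = tab.loc[s.daughter_ids[1], "mb_flux_per_s"]
            assert fa + fb == pytest.approx(tab.loc[i, "mb_flux_per_s"], rel=1e-12)
        assert mb.terminal_fluxes().sum() == pytest.approx(44.0, rel=1e-8)

    def test_symmetric_tree_equal_fluxes_no_zeros(self, balanced_tree):
        state = solve(balanced_tree, BoundaryConditions(12.0, 0.42))
        mb = propagate(state, balanced_tree, 44.0)
        f = mb.terminal_fluxes()
        assert np.ptp(f.to_numpy()) < 1e-12 * f.mean()
        assert mb.zero_flux_terminal_fraction == 0.0

    def test_resident_count_is_flux_weighted_transit(self, small_tree, small_state):
        mb = propagate(small_state, small_tree, 44.0)
        manual = 0.0
        for i in small_tree.segments:
            flux = mb.table.loc[i, "mb_flux_per_s"]
            L_mm = small_tree.segments[i].length / 1000.0
            v = small_state.table.loc[i, "rbc_velocity_mm_s"]
            manual += flux * L_mm / v
        assert mb.arteriolar_resident_total == pytest.approx(manual, rel=1e-12)

    def test_blood_velocity_rule_gives_longer_transits(self, small_tree, small_state):
        fast = propagate(small_state, small_tree, 44.0,
                         MicrobubbleParams(mb_velocity_rule="rbc_velocity"))
        slow = propagate(small_state, small_tree, 44.0,
                         MicrobubbleParams(mb_velocity_rule="blood_velocity"))
        assert slow.arteriolar_resident_total > fast.arteriolar_resident_total


class TestCapillaryCensus:
    def test_uniform_capillary_allocation(self, small_tree, small_state):
        mb = propagate(small_state, small_tree, 44.0)
        bed = CapillaryBedParams(n_capillaries=2.2e4)
        census = capillary_census(mb, small_state, bed)
        assert census["capillaries_per_terminal"] == pytest.approx(
            2.2e4 / small_tree.n_terminals)
        assert census["total_flux_per_s"] == pytest.approx(44.0, rel=1e-8)

    def test_doubling_capillary_length_doubles_residency(self, small_tree, small_state):
        mb = propagate(small_state, small_tree, 44.0)
        c1 = capillary_census(mb, small_state, CapillaryBedParams(capillary_length_um=400))
        c2 = capillary_census(mb, small_state, CapillaryBedParams(capillary_length_um=800))
        assert c2["total_resident"] == pytest.approx(2 * c1["total_resident"], rel=1e-12)

    def test_default_214_terminal_allocation(self):
        assert 2.2e4 / 214 == pytest.approx(102.8, abs=0.05)


class TestParamValidation:
    def test_rejects_weaker_than_rbc_cutoff(self):
        with pytest.raises(ValueError):
            MicrobubbleParams(cutoff_inflation=0.5)
        with pytest.raises(ValueError):
            MicrobubbleParams(mb_velocity_rule="warp")
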