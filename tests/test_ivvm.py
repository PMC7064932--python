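"""Tests for the intravital capillary hemodynamics derivation chain."""

import math

import numpy as np
import pandas as pd
import pytest

from capnet.ivvm import (CapillaryRecord, classify_flow, derive_velocities_and_flows,
                         derived_to_frame, functional_capillary_density, group_stats,
                         so2_from_intensities, supply_rate, tube_hematocrit)


def _record(v=0.15, ld=40.0, D=5.0, **kw):
    return CapillaryRecord(capillary_id="c1", animal_id="a1", condition="baseline",
                           velocity_mm_s=np.asarray(v, dtype=float),
                           lineal_density_per_mm=np.asarray(ld, dtype=float),
                           diameter_um=D, segment_length_um=150.0, **kw)


class TestTubeHematocrit:
    def test_hand_arithmetic(self):
        # 60 RBC/mm of a 5 um capillary: 60*65 um^3 per 19635 um^3 of lumen
        assert tube_hematocrit(60.0, 5.0) == pytest.approx(60 * 65 / 19634.95, rel=1e-4)

    def test_zero_and_linearity(self):
        assert tube_hematocrit(0.0, 5.0) == 0.0
        assert tube_hematocrit(80.0, 5.0) == pytest.approx(2 * tube_hematocrit(40.0, 5.0))

    def test_impossible_hematocrit_flagged(self):
        with pytest.raises(ValueError, match="> 1"):
            tube_hematocrit(1000.0, 3.0)


class TestSupplyRate:
    def test_product(self):
        assert supply_rate(0.15, 40.0) == pytest.approx(6.0)
        assert supply_rate(0.0, 40.0) == 0.0

    def test_frame_wise_ordering_matters_under_covariation(self):
        v = np.array([0.1, 0.3])
        ld = np.array([60.0, 20.0])
        frame_wise = supply_rate(v, ld)               # mean of products
        naive = v.mean() * ld.mean()                  # product of means
        assert frame_wise == pytest.approx(6.0)
        assert naive == pytest.approx(8.0)
        assert frame_wise != naive


class TestDeriveVelocitiesAndFlows:
    def test_full_chain_against_independent_oracle(self):
        rec = _record(v=0.15, ld=40.0, D=5.0)
        d = derive_velocities_and_flows(rec)

        # independently scripted chain: bisection inverse of the Fahraeus law
        ht = 40 * 65 / (math.pi * 2.5**2 * 1000)

        def tube(hd):
            shape = 1 + 1.7 * math.exp(-0.415 * 5) - 0.6 * math.exp(-0.011 * 5)
            return hd * (hd + (1 - hd) * shape)

        lo, hi = ht, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if tube(mid) < ht:
                lo = mid
            else:
                hi = mid
        hd = 0.5 * (lo + hi)
        v_blood = ht / hd * 0.15
        v_plasma = (v_blood - ht * 0.15) / (1 - ht)
        q_blood = v_blood * 1000 * math.pi * 2.5**2 / 1000
        assert d.tube_hct == pytest.approx(ht, rel=1e-9)
        assert d.discharge_hct == pytest.approx(hd, abs=1e-6)
        assert d.blood_velocity_mm_s == pytest.approx(v_blood, rel=1e-6)
        assert d.plasma_velocity_mm_s == pytest.approx(v_plasma, rel=1e-6)
        assert d.q_rbc_pl_s == pytest.approx(6 * 65 / 1000)       # 0.39 pL/s
        assert d.q_blood_pl_s == pytest.approx(q_blood, rel=1e-6)
        assert d.q_plasma_pl_s == pytest.approx(q_blood - 0.39, rel=1e-5)

    def test_flow_balance_and_velocity_ordering(self):
        d = derive_velocities_and_flows(_record(v=0.2, ld=55.0, D=4.5))
        assert d.q_blood_pl_s == pytest.approx(d.q_rbc_pl_s + d.q_plasma_pl_s, rel=1e-9)
        assert d.plasma_velocity_mm_s < d.blood_velocity_mm_s < d.mean_velocity_mm_s

    def test_dilute_limit_plasma_velocity_approaches_blood(self):
        d = derive_velocities_and_flows(_record(v=0.15, ld=0.5, D=5.0))
        assert d.plasma_velocity_mm_s == pytest.approx(d.blood_velocity_mm_s, rel=1e-2)

    def test_scaling_velocities_scales_flows(self):
        d1 = derive_velocities_and_flows(_record(v=0.15, ld=40.0))
        d2 = derive_velocities_and_flows(_record(v=0.30, ld=40.0))
        assert d2.q_rbc_pl_s == pytest.approx(2 * d1.q_rbc_pl_s)
        assert d2.q_blood_pl_s == pytest.approx(2 * d1.q_blood_pl_s, rel=1e-9)
        assert d2.tube_hct == d1.tube_hct
        assert d2.discharge_hct == pytest.approx(d1.discharge_hct, abs=1e-12)


class TestSO2:
    def test_round_trip_with_identity_calibration(self):
        # synthesize intensities for a known OD ratio
        so2_true = 0.65
        od454 = 0.30
        od442 = so2_true * od454
        i_rbc442 = 100.0 / 10**od442
        i_rbc454 = 100.0 / 10**od454
        got = so2_from_intensities(100.0, i_rbc442, 100.0, i_rbc454)
        assert got == pytest.approx(so2_true, abs=1e-9)

    def test_hand_value_and_clamping(self):
        # OD442 = log10(2), OD454 = log10(4) -> ratio = 0.5
        assert so2_from_intensities(200, 100, 400, 100) == pytest.approx(0.5)
        assert so2_from_intensities(1000, 100, 110, 100) == 1.0   # clamped

    def test_degenerate_reference_excluded(self):
        with pytest.raises(ValueError, match="undefined"):
            so2_from_intensities(120, 100, 100, 100)
        with pytest.raises(ValueError):
            so2_from_intensities(-1, 100, 100, 90)


class TestClassifyFlow:
    def test_continuous(self):
        v = np.full(700, 0.2)
        assert classify_flow(v) == "continuous"

    def test_stopped_for_full_window(self):
        assert classify_flow(np.zeros(700)) == "stopped"

    def test_reversal_is_intermittent(self):
        v = np.full(700, 0.2)
        v[400:] = -0.2
        assert classify_flow(v) == "intermittent"

    def test_brief_stop_is_intermittent(self):
        v = np.full(700, 0.2)
        v[100:163] = 0.0                               # 3 s pause
        assert classify_flow(v) == "intermittent"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="30"):
            classify_flow(np.full(300, 0.2))


class TestFunctionalCapillaryDensity:
    def test_reference_lines(self):
        # 9 capillaries over three 150 um lines -> 20 per mm
        assert functional_capillary_density([3, 3, 3], 0.150) == pytest.approx(20.0)
        assert functional_capillary_density([0, 0, 0], 0.150) == 0.0

    def test_scale_invariance(self):
        a = functional_capillary_density([4, 2, 3], 0.150)
        b = functional_capillary_density([8, 4, 6], 0.300)
        assert a == pytest.approx(b)


class TestGroupStats:
    def _frame(self, base, clamp):
        rows = []
        for i, (b, c) in enumerate(zip(base, clamp)):
            for cond, q in (("baseline", b), ("clamp", c)):
                rows.append({"capillary_id": f"c{i}", "condition": cond,
                             "q_rbc_pl_s": q, "q_plasma_pl_s": 4 * q,
                             "mean_velocity_mm_s": q / 2})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_null_result(self):
        df = self._frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = group_stats(df)
        assert out["paired_t"]["q_rbc_pl_s"]["t"] == 0.0
        assert out["paired_t"]["q_rbc_pl_s"]["mean_pct_change"] == 0.0

    def test_three_pair_t_statistic_matches_closed_form(self):
        # differences 1, 2, 3: mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        df = self._frame([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        t = group_stats(df)["paired_t"]["q_rbc_pl_s"]["t"]
        assert t == pytest.approx(2 / (1 / math.sqrt(3)), rel=1e-12)

    def test_programmed_negative_flow_dependence_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(-1, 0.5, 80)
        pct = 150 - 120 * base + rng.normal(0, 10, 80)
        clamp = base * (1 + pct / 100)
        out = group_stats(self._frame(base, clamp))
        reg = out["rbc_flow_pct_change_regression"]
        assert reg["slope"] < 0
        assert reg["slope_p"] < 0.01
        assert reg["r2"] > 0.3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            group_stats(self._frame([1.0], [2.0]))
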