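"""Paired baseline / simulated-hyperinsulinemia network workflow.

Builds the baseline (BN) arteriolar tree, derives the simulated
hyperinsulinemia (SHI) tree from it by rescaling every bifurcation's
asymmetry (same topology, same segment lengths — a paired comparison),
solves two-phase flow under each condition's pressure drop, propagates
microbubbles with parameters frozen across the pair, and runs the
capillary-bed census.

This is the workflow behind the headline model numbers: terminal tube
hematocrit, the fraction of terminal arterioles with zero bubble flux,
and arteriolar / capillary resident bubble totals under both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .netgen import ArteriolarTree, NetworkSpec, build_tree, rescale_asymmetry
from .flow_solver import BoundaryConditions, NetworkState, solve, summarize_terminals
from .microbubble import (CapillaryBedParams, MicrobubbleParams, MicrobubbleState,
                          capillary_census, inlet_mb_rate, propagate)
from .rheology import DEFAULT_RHEOLOGY, RheologyParams

__all__ = ["ConditionResult", "StudyPair", "run_condition_pair", "DEFAULT_BN_SPEC",
           "SHI_ASYMMETRY_MEAN", "BN_BC", "SHI_BC"]

DEFAULT_BN_SPEC = NetworkSpec()            # asymmetry 0.07, 75 um root, ~214 terminals
SHI_ASYMMETRY_MEAN = 0.055
BN_BC = BoundaryConditions(pressure_drop_mmHg=12.0, inlet_discharge_hct=0.42)
SHI_BC = BoundaryConditions(pressure_drop_mmHg=18.0, inlet_discharge_hct=0.42)


@dataclass
class ConditionResult:
    tree: ArteriolarTree
    state: NetworkState
    mb: MicrobubbleState
    census: dict
    terminal_summary: dict

    @property
    def mean_terminal_tube_hct(self) -> float:
        return self.terminal_summary["tube_hct"]["mean"]

    @property
    def root_tube_hct(self) -> float:
        return float(self.state.table.loc[self.state.meta["root_id"], "tube_hct"])


@dataclass
class StudyPair:
    bn: ConditionResult
    shi: ConditionResult

    @property
    def inlet_flow_ratio(self) -> float:
        return self.shi.state.inlet_blood_flow_nl_s / self.bn.state.inlet_blood_flow_nl_s

    def summary(self) -> dict:
        bn, shi = self.bn, self.shi
        zero_bn = bn.mb.zero_flux_terminal_fraction
        zero_shi = shi.mb.zero_flux_terminal_fraction
        return {
            "inlet_blood_flow_ratio": self.inlet_flow_ratio,
            "root_tube_hct_bn": bn.root_tube_hct,
            "mean_terminal_tube_hct_bn": bn.mean_terminal_tube_hct,
            "mean_terminal_tube_hct_shi": shi.mean_terminal_tube_hct,
            "zero_mb_terminal_pct_bn": 100.0 * zero_bn,
            "zero_mb_terminal_pct_shi": 100.0 * zero_shi,
            "pct_increase_terminals_with_mb": 100.0 * ((1 - zero_shi) - (1 - zero_bn)) / (1 - zero_bn),
            "arteriolar_resident_bn": bn.mb.arteriolar_resident_total,
            "arteriolar_resident_shi": shi.mb.arteriolar_resident_total,
            "capillary_resident_bn": bn.census["total_resident"],
            "capillary_resident_shi": shi.census["total_resident"],
            "capillary_resident_pct_increase":
                100.0 * (shi.census["total_resident"] / bn.census["total_resident"] - 1.0),
        }


def _run_condition(tree: ArteriolarTree, bc: BoundaryConditions, inlet_rate: float,
                   mb_params: MicrobubbleParams, bed: CapillaryBedParams,
                   rheo: RheologyParams, state: NetworkState | None = None) -> ConditionResult:
    if state is None:
        state = solve(tree, bc, rheo)
    mb = propagate(state, tree, inlet_rate, mb_params, rheo)
    census = capillary_census(mb, state, bed, mb_params, rheo)
    return ConditionResult(tree=tree, state=state, mb=mb, census=census,
                           terminal_summary=summarize_terminals(state))


def run_condition_pair(
    spec: NetworkSpec = DEFAULT_BN_SPEC,
    shi_asymmetry_mean: float = SHI_ASYMMETRY_MEAN,
    bn_bc: BoundaryConditions = BN_BC,
    shi_bc: BoundaryConditions = SHI_BC,
    mb_params: MicrobubbleParams | None = None,
    bed: CapillaryBedParams | None = None,
    rheo: RheologyParams = DEFAULT_RHEOLOGY,
) -> StudyPair:
    """Run the full BN / SHI paired workflow with frozen bubble parameters.

    The inlet bubble rate under BN comes from the capillary bed's RBC demand
    divided by the bubble:RBC number ratio; under SHI it is scaled by the
    solved inlet RBC flow ratio (the infusate composition is unchanged, so
    bubble supply tracks RBC supply).
    """
    mb_params = mb_params or MicrobubbleParams()
    bed = bed or CapillaryBedParams()

    bn_tree = build_tree(spec)
    shi_tree = rescale_asymmetry(bn_tree, shi_asymmetry_mean)

    bn_state = solve(bn_tree, bn_bc, rheo)
    shi_state = solve(shi_tree, shi_bc, rheo)

    bn_rate = inlet_mb_rate(bed, mb_params)
    shi_rate = inlet_mb_rate(bed, mb_params, state=shi_state, reference_state=bn_state)

    bn = _run_condition(bn_tree, bn_bc, bn_rate, mb_params, bed, rheo, state=bn_state)
    shi = _run_condition(shi_tree, shi_bc, shi_rate, mb_params, bed, rheo, state=shi_state)
    return StudyPair(bn=bn, shi=shi)
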