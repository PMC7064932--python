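"""Microbubble transport through a solved arteriolar network.

Microbubbles are modelled as an expectation flux (bubbles/s), not as
discrete particles: they are ~1:6000 as numerous as RBCs, so each segment
carries a mean flux and a mean resident count (flux x transit time).

Above a feed diameter of 30 um, bubbles are assumed to partition at
diverging bifurcations exactly like RBCs. Below 30 um they partition *more*
preferentially toward the higher-flow daughter: the same logit law with an
inflated zero-flux cutoff and a steeper slope. Because the cutoff produces
exact zeros, entire subtrees downstream of a starved branch carry exactly
zero bubble flux — the mechanism by which a reduction in bifurcation
asymmetry redistributes bubbles into many more terminal arterioles.

The capillary-bed census assumes the bed's capillaries are spread uniformly
across terminal arterioles, each capillary receiving an equal share of its
terminal's flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .netgen import ArteriolarTree
from .flow_solver import NetworkState
from .rheology import DEFAULT_RHEOLOGY, RheologyParams, rbc_split, tube_hct

__all__ = [
    "MicrobubbleParams",
    "CapillaryBedParams",
    "MicrobubbleState",
    "inlet_mb_rate",
    "mb_split",
    "propagate",
    "capillary_census",
]


@dataclass(frozen=True)
class MicrobubbleParams:
    """Microbubble behaviour knobs.

    ``cutoff_inflation`` and ``slope_gain`` shape the small-vessel
    preferential law relative to the RBC phase-separation law; they were
    calibrated once against the baseline network's zero-bubble-flux terminal
    fraction and are frozen (see docs/methods.md).
    """

    mb_to_rbc_ratio: float = 1.0 / 6000.0
    rbc_like_diameter_threshold_um: float = 30.0
    cutoff_inflation: float = 23.44
    slope_gain: float = 0.3
    reference_hd: float = 0.42               # hematocrit at which the cutoff scale is anchored
    hd_sensitivity: float = 0.5              # 0: fixed cutoff; 1: cutoff tracks local (1-HD)
    mb_velocity_rule: str = "rbc_velocity"   # or "blood_velocity"

    def __post_init__(self) -> None:
        if self.mb_to_rbc_ratio <= 0 or self.rbc_like_diameter_threshold_um <= 0:
            raise ValueError("ratio and threshold must be positive")
        if self.cutoff_inflation < 1.0 or self.slope_gain <= 0.0:
            raise ValueError("small-vessel cutoff must be at least the RBC cutoff and the "
                             "slope gain positive")
        if self.mb_velocity_rule not in ("rbc_velocity", "blood_velocity"):
            raise ValueError(f"unknown mb_velocity_rule {self.mb_velocity_rule!r}")


@dataclass(frozen=True)
class CapillaryBedParams:
    """Capillary bed fed by the terminal arterioles."""

    n_capillaries: float = 2.2e4
    reference_supply_rate_rbc_s: float = 12.0   # typical per-capillary RBC supply
    capillary_length_um: float = 706.0          # effective path length through the bed
    capillary_diameter_um: float = 4.5

    def __post_init__(self) -> None:
        if min(self.n_capillaries, self.reference_supply_rate_rbc_s,
               self.capillary_length_um, self.capillary_diameter_um) <= 0:
            raise ValueError("capillary-bed parameters must be positive")


@dataclass
class MicrobubbleState:
    """Per-segment bubble flux and resident counts after propagation.

    ``table``: one row per segment with mb_flux_per_s, mb_velocity_mm_s,
    transit_time_s, resident_count, is_terminal.
    """

    table: pd.DataFrame
    inlet_rate_per_s: float
    meta: dict = field(default_factory=dict)

    def terminal_fluxes(self) -> pd.Series:
        return self.table.loc[self.table["is_terminal"], "mb_flux_per_s"]

    @property
    def zero_flux_terminal_fraction(self) -> float:
        f = self.terminal_fluxes()
        return float((f == 0.0).mean())

    @property
    def arteriolar_resident_total(self) -> float:
        return float(self.table["resident_count"].sum())


def inlet_mb_rate(bed: CapillaryBedParams, params: MicrobubbleParams = MicrobubbleParams(),
                  state: NetworkState | None = None,
                  reference_state: NetworkState | None = None) -> float:
    """Microbubble supply rate (s^-1) entering the first-order arteriole.

    The bed's RBC demand, ``n_capillaries x reference_supply_rate``, sets the
    network RBC supply rate; the bubble rate is that divided by the
    RBC:bubble number ratio (~6000). If ``state`` and ``reference_state``
    are given, the rate is additionally scaled by their inlet RBC flow
    ratio: the bubble:RBC ratio is a property of the infused blood, so a
    network driven to higher flow carries proportionally more bubbles.
    """
    rate = bed.n_capillaries * bed.reference_supply_rate_rbc_s * params.mb_to_rbc_ratio
    if state is not None:
        if reference_state is None:
            raise ValueError("reference_state required to scale the inlet rate")
        rate *= state.inlet_rbc_flow_nl_s / reference_state.inlet_rbc_flow_nl_s
    return rate


def mb_split(FQB: float, Df: float, Da: float, Db: float, HD_feed: float,
             params: MicrobubbleParams = MicrobubbleParams(),
             rheo: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Fraction of feed microbubble flux entering daughter *a*.

    Identical to the RBC phase-separation law for feeds wider than the
    threshold. Below it, the split is strictly more sigmoidal: the logit
    slope is multiplied by ``slope_gain`` and the zero-flux cutoff is
    inflated to ``cutoff_inflation`` times the RBC cutoff *evaluated at the
    threshold diameter* — rigid bubbles cannot exploit the near-wall plasma
    layer the way deformable RBCs do, so their exclusion margin stops
    shrinking with vessel size once the vessel is bubble-scale.
    Complementary daughters sum to 1 and sub-cutoff branches receive
    exactly zero.
    """
    thr = params.rbc_like_diameter_threshold_um
    if Df > thr:
        return rbc_split(FQB, Df, Da, Db, HD_feed, rheo)
    # Bubble exclusion is geometric (a rigid sphere vs the near-wall plasma
    # layer), so below the threshold the cutoff is pinned to the threshold
    # diameter scale; hd_sensitivity sets how much it tracks the local
    # plasma fraction (plasma-rich feeds exclude bubbles more strongly).
    hd_factor = ((1.0 - HD_feed) / (1.0 - params.reference_hd)) ** params.hd_sensitivity
    x0_mb = min(params.cutoff_inflation * rheo.ps_x0_coeff
                * (1.0 - params.reference_hd) * hd_factor / thr, 0.499)
    return rbc_split(FQB, Df, Da, Db, HD_feed, rheo,
                     x0_value=x0_mb, slope_scale=params.slope_gain)


def propagate(state: NetworkState, tree: ArteriolarTree, inlet_rate: float,
              params: MicrobubbleParams = MicrobubbleParams(),
              rheo: RheologyParams = DEFAULT_RHEOLOGY) -> MicrobubbleState:
    """Propagate the inlet bubble flux through the solved network.

    Bubble flux is conserved at every node; per-segment resident count is
    flux x (length / bubble velocity), with the bubble velocity equal to the
    segment's RBC velocity by default (bubbles ride near the centerline).
    """
    tab = state.table
    vcol = "rbc_velocity_mm_s" if params.mb_velocity_rule == "rbc_velocity" else "blood_velocity_mm_s"
    flux = pd.Series(0.0, index=tab.index)
    flux.loc[state.meta["root_id"]] = inlet_rate
    order = [state.meta["root_id"]]
    stack = [state.meta["root_id"]]
    while stack:
        i = stack.pop()
        s = tree.segments[i]
        if s.daughter_ids is None:
            continue
        ia, ib = s.daughter_ids
        fqb_a = tab.loc[ia, "blood_flow_nl_s"] / tab.loc[i, "blood_flow_nl_s"]
        frac_a = mb_split(fqb_a, tab.loc[i, "diameter_um"], tab.loc[ia, "diameter_um"],
                          tab.loc[ib, "diameter_um"], tab.loc[i, "discharge_hct"], params, rheo)
        flux.loc[ia] = flux.loc[i] * frac_a
        flux.loc[ib] = flux.loc[i] * (1.0 - frac_a)
        stack.extend([ia, ib])
        order.extend([ia, ib])

    v = tab[vcol]                                  # mm/s
    transit = (tab["length_um"] / 1000.0) / v      # s
    out = pd.DataFrame({
        "mb_flux_per_s": flux,
        "mb_velocity_mm_s": v,
        "transit_time_s": transit,
        "resident_count": flux * transit,
        "is_terminal": tab["is_terminal"],
    })
    return MicrobubbleState(table=out, inlet_rate_per_s=inlet_rate,
                            meta={"params": params.__dict__.copy(), "root_id": state.meta["root_id"]})


def capillary_census(mb_state: MicrobubbleState, state: NetworkState,
                     bed: CapillaryBedParams,
                     params: MicrobubbleParams = MicrobubbleParams(),
                     rheo: RheologyParams = DEFAULT_RHEOLOGY) -> dict:
    """Census of microbubbles resident in the capillary bed.

    Capillaries are distributed uniformly over terminal arterioles; each
    receives an equal share of its terminal's blood and bubble flux. The
    per-capillary bubble velocity follows the configured velocity rule at
    the capillary diameter (RBC velocity by default, via the Fahraeus ratio
    at the capillary diameter).

    Returns a dict with the per-terminal table, capillaries per terminal,
    and the bed-wide resident total.
    """
    term = state.terminals()
    if (term["blood_flow_nl_s"] <= 0).any():
        raise ValueError("terminal with zero blood flow: census undefined")
    n_term = len(term)
    n_cap_per_term = bed.n_capillaries / n_term
    flux_cap = mb_state.terminal_fluxes() / n_cap_per_term          # bubbles/s per capillary
    q_cap_nl = term["blood_flow_nl_s"] / n_cap_per_term
    area_um2 = np.pi * (bed.capillary_diameter_um / 2.0) ** 2
    # nL/s -> um^3/s is 1e6; velocity um/s -> mm/s is 1e-3
    v_blood_cap = q_cap_nl * 1e6 / area_um2 * 1e-3                  # mm/s
    if params.mb_velocity_rule == "rbc_velocity":
        hd = term["discharge_hct"]
        ht = np.array([tube_hct(bed.capillary_diameter_um, h, rheo) for h in hd])
        v_mb = v_blood_cap * hd.to_numpy() / ht
    else:
        v_mb = v_blood_cap.to_numpy()
    transit = (bed.capillary_length_um / 1000.0) / v_mb             # s
    resident_per_cap = flux_cap.to_numpy() * transit
    per_term = pd.DataFrame({
        "mb_flux_per_capillary_s": flux_cap,
        "capillary_blood_velocity_mm_s": v_blood_cap,
        "capillary_mb_velocity_mm_s": v_mb,
        "capillary_transit_s": transit,
        "resident_per_capillary": resident_per_cap,
        "resident_total": resident_per_cap * n_cap_per_term,
    }, index=term.index)
    return {
        "per_terminal": per_term,
        "capillaries_per_terminal": n_cap_per_term,
        "total_resident": float(per_term["resident_total"].sum()),
        "total_flux_per_s": float(mb_state.terminal_fluxes().sum()),
    }
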