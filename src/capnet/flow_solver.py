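"""Steady-state two-phase (blood + RBC) flow on an arteriolar tree.

The driving boundary condition is a fixed pressure drop between the inlet
node of the root arteriole and the outlets of *all* terminal arterioles
(equal outlet pressures). On a tree this admits an exact series-parallel
reduction: each subtree collapses to an effective Poiseuille resistance,
so pressures and flows are computed without a general sparse solve.

Hematocrit enters twice and makes the problem non-linear:

* the apparent viscosity of each segment depends on its discharge
  hematocrit (HD), so resistances depend on the hematocrit field; and
* HD is redistributed at every diverging bifurcation by the empirical
  phase-separation law, which depends on the fractional blood flows.

The solver therefore iterates: resistances -> flows -> hematocrit
propagation root-to-leaves -> resistances, with under-relaxation on the
hematocrit update (the phase-separation cutoff can make the undamped map
oscillate). Convergence is declared when the largest relative change in
segment HD and blood flow falls below ``tol`` (default 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .netgen import ArteriolarTree
from .rheology import DEFAULT_RHEOLOGY, RheologyParams, rbc_split, relative_viscosity, tube_hct

__all__ = ["BoundaryConditions", "NetworkState", "solve", "summarize_terminals"]


@dataclass(frozen=True)
class BoundaryConditions:
    """Pressure drop (mm Hg) across the tree and inlet discharge hematocrit."""

    pressure_drop_mmHg: float = 12.0   # 12 baseline, 18 simulated hyperinsulinemia
    inlet_discharge_hct: float = 0.42

    def __post_init__(self) -> None:
        if self.pressure_drop_mmHg <= 0:
            raise ValueError("pressure drop must be positive")
        if not (0.0 < self.inlet_discharge_hct < 1.0):
            raise ValueError("inlet hematocrit must be in (0, 1)")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float, oscillating: bool = False):
        super().__init__(message)
        self.residual = residual
        self.oscillating = oscillating


@dataclass
class NetworkState:
    """Converged per-segment hemodynamics.

    ``table`` has one row per segment (indexed by segment id) with columns:
    diameter_um, length_um, is_terminal, pressure_in_mmHg, pressure_out_mmHg,
    blood_flow_nl_s, rbc_flow_nl_s, plasma_flow_nl_s, discharge_hct,
    tube_hct, blood_velocity_mm_s, rbc_velocity_mm_s, resistance_Pa_s_m3.
    """

    table: pd.DataFrame
    iterations: int
    residual: float
    meta: dict = field(default_factory=dict)

    @property
    def inlet_blood_flow_nl_s(self) -> float:
        return float(self.table.loc[self.meta["root_id"], "blood_flow_nl_s"])

    @property
    def inlet_rbc_flow_nl_s(self) -> float:
        return float(self.table.loc[self.meta["root_id"], "rbc_flow_nl_s"])

    def terminals(self) -> pd.DataFrame:
        return self.table[self.table["is_terminal"]]


def _topo_order(tree: ArteriolarTree) -> list[int]:
    """Segment ids root-first (parents before daughters)."""
    order, stack = [], [tree.root_id]
    while stack:
        i = stack.pop()
        order.append(i)
        s = tree.segments[i]
        if s.daughter_ids is not None:
            stack.extend(s.daughter_ids)
    return order


def solve(
    tree: ArteriolarTree,
    bc: BoundaryConditions,
    rheo: RheologyParams = DEFAULT_RHEOLOGY,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> NetworkState:
    """Solve for the two-phase steady state of the tree under ``bc``.

    Raises
    ------
    ConvergenceError
        If the damped fixed point has not converged after ``max_iter``
        sweeps; the error carries the last residual and flags oscillation
        (residual not decreasing over the final sweeps).
    """
    tree.validate()
    order = _topo_order(tree)
    ids = sorted(tree.segments)
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    D = np.array([tree.segments[i].diameter for i in ids])          # um
    L = np.array([tree.segments[i].length for i in ids])            # um
    is_term = np.array([tree.segments[i].is_terminal for i in ids])

    dp_pa = bc.pressure_drop_mmHg * units.MMHG_TO_PA
    mu_plasma = rheo.plasma_viscosity_mPa_s * 1e-3                  # Pa*s
    D_m, L_m = D * units.UM_TO_M, L * units.UM_TO_M
    geom = 128.0 * L_m / (np.pi * D_m**4)                           # R = geom * mu

    HD = np.full(n, bc.inlet_discharge_hct)
    Q = np.zeros(n)                                                 # m^3/s
    residual, history = np.inf, []
    for it in range(1, max_iter + 1):
        mu = np.array([relative_viscosity(D[k], HD[k], rheo) for k in range(n)]) * mu_plasma
        R = geom * mu
        # series-parallel collapse, leaves to root
        Reff = np.empty(n)
        for i in reversed(order):
            k = idx[i]
            s = tree.segments[i]
            if s.daughter_ids is None:
                Reff[k] = R[k]
            else:
                ka, kb = idx[s.daughter_ids[0]], idx[s.daughter_ids[1]]
                Reff[k] = R[k] + 1.0 / (1.0 / Reff[ka] + 1.0 / Reff[kb])
        # flows top-down: flow through a subtree = (pressure at its top) / Reff
        Q_new = np.empty(n)
        Q_new[idx[tree.root_id]] = dp_pa / Reff[idx[tree.root_id]]
        for i in order:
            s = tree.segments[i]
            if s.daughter_ids is None:
                continue
            k = idx[i]
            ka, kb = idx[s.daughter_ids[0]], idx[s.daughter_ids[1]]
            ga, gb = 1.0 / Reff[ka], 1.0 / Reff[kb]
            Q_new[ka] = Q_new[k] * ga / (ga + gb)
            Q_new[kb] = Q_new[k] * gb / (ga + gb)
        # hematocrit propagation root -> leaves via the phase-separation law
        HD_new = np.empty(n)
        HD_new[idx[tree.root_id]] = bc.inlet_discharge_hct
        for i in order:
            s = tree.segments[i]
            if s.daughter_ids is None:
                continue
            k = idx[i]
            ka, kb = idx[s.daughter_ids[0]], idx[s.daughter_ids[1]]
            fqb_a = Q_new[ka] / Q_new[k]
            fqe_a = rbc_split(fqb_a, D[k], D[idx[s.daughter_ids[0]]], D[idx[s.daughter_ids[1]]],
                              HD_new[k], rheo)
            qrbc = HD_new[k] * Q_new[k]
            HD_new[ka] = min(fqe_a * qrbc / Q_new[ka], 0.99)
            HD_new[kb] = min((1.0 - fqe_a) * qrbc / Q_new[kb], 0.99)
        dq = np.max(np.abs(Q_new - Q) / np.maximum(np.abs(Q_new), 1e-300)) if it > 1 else np.inf
        dh = np.max(np.abs(HD_new - HD))
        residual = max(dh, dq if np.isfinite(dq) else 1.0)
        history.append(residual)
        Q = Q_new
        HD = HD + damping * (HD_new - HD) if it > 1 else HD_new
        if residual < tol:
            break
    else:
        oscillating = len(history) > 20 and history[-1] > 0.5 * history[-20]
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (residual {residual:.3e})"
            + ("; iteration appears to oscillate despite damping" if oscillating else ""),
            residual, oscillating)

    # final exact propagation with the converged flow field, so blood and RBC
    # flux are conserved at every node to machine precision in the output
    HD = np.empty(n)
    HD[idx[tree.root_id]] = bc.inlet_discharge_hct
    for i in order:
        s = tree.segments[i]
        if s.daughter_ids is None:
            continue
        k = idx[i]
        ka, kb = idx[s.daughter_ids[0]], idx[s.daughter_ids[1]]
        fqe_a = rbc_split(Q[ka] / Q[k], D[k], D[ka], D[kb], HD[k], rheo)
        HD[ka] = fqe_a * HD[k] * Q[k] / Q[ka]
        HD[kb] = (1.0 - fqe_a) * HD[k] * Q[k] / Q[kb]
    HT = np.array([tube_hct(D[k], HD[k], rheo) for k in range(n)])
    q_nl = Q * units.M3_S_TO_NL_S
    qrbc_nl = q_nl * HD
    area_m2 = np.pi * (D_m / 2.0) ** 2
    v_blood = Q / area_m2 * units.M_S_TO_MM_S                       # mm/s
    with np.errstate(divide="ignore"):
        v_rbc = np.where(HT > 0, v_blood * HD / HT, v_blood)

    # node pressures: accumulate drops along each segment
    p_in = np.empty(n)
    p_out = np.empty(n)
    mu = np.array([relative_viscosity(D[k], HD[k], rheo) for k in range(n)]) * mu_plasma
    R = geom * mu
    p_in[idx[tree.root_id]] = bc.pressure_drop_mmHg
    for i in order:
        k = idx[i]
        s = tree.segments[i]
        if s.parent_id is not None:
            p_in[k] = p_out[idx[s.parent_id]]
        p_out[k] = p_in[k] - (Q[k] * R[k]) / units.MMHG_TO_PA

    table = pd.DataFrame(
        {
            "diameter_um": D,
            "length_um": L,
            "is_terminal": is_term,
            "pressure_in_mmHg": p_in,
            "pressure_out_mmHg": p_out,
            "blood_flow_nl_s": q_nl,
            "rbc_flow_nl_s": qrbc_nl,
            "plasma_flow_nl_s": q_nl - qrbc_nl,
            "discharge_hct": HD,
            "tube_hct": HT,
            "blood_velocity_mm_s": v_blood,
            "rbc_velocity_mm_s": v_rbc,
            "resistance_Pa_s_m3": R,
        },
        index=pd.Index(ids, name="segment_id"),
    )
    meta = {
        "root_id": tree.root_id,
        "bc": {"pressure_drop_mmHg": bc.pressure_drop_mmHg, "inlet_discharge_hct": bc.inlet_discharge_hct},
        "rheology": rheo.to_dict(),
    }
    return NetworkState(table=table, iterations=it, residual=float(residual), meta=meta)


def summarize_terminals(state: NetworkState) -> dict:
    """Distribution summary over terminal arterioles.

    Returns per-terminal RBC flow, plasma flow and tube hematocrit plus
    median / quartile / extreme statistics for each.
    """
    term = state.terminals()
    out = {"table": term[["rbc_flow_nl_s", "plasma_flow_nl_s", "tube_hct"]].copy()}
    for col in ("rbc_flow_nl_s", "plasma_flow_nl_s", "tube_hct"):
        x = term[col].to_numpy()
        out[col] = {
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "q1": float(np.percentile(x, 25)),
            "q3": float(np.percentile(x, 75)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
    return out
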