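"""Derived capillary hemodynamics from intravital video microscopy (IVVM).

IVVM yields, per capillary and per video frame, the RBC velocity (mm/s) and
lineal density (RBC/mm), plus the capillary diameter and segment length from
a functional image. Everything else is derived:

* tube hematocrit: lineal density x RBC volume / vessel volume per length;
* supply rate: frame-wise velocity x lineal density, then time-averaged
  (the aggregation order matters when velocity and density covary);
* discharge hematocrit: numerical inverse of the Fahraeus relation at the
  capillary diameter;
* blood velocity = (HT/HD) x RBC velocity; plasma velocity from the
  hematocrit-weighted velocity identity; volumetric RBC / plasma / blood
  flows in pL/s;
* hemoglobin O2 saturation from two-wavelength optical densities;
* a 30-s flow-state classification (continuous / intermittent / stopped)
  and functional capillary density; and
* the study-level statistics: paired t tests, percent changes, and the
  capillary-level regression of percent flow change on baseline flow with
  a Wald-Wolfowitz runs test on its residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.sandbox.stats.runs import runstest_1samp

from . import units
from .rheology import DEFAULT_RHEOLOGY, RheologyParams, discharge_hct

__all__ = [
    "CapillaryRecord",
    "DerivedHemodynamics",
    "tube_hematocrit",
    "supply_rate",
    "derive_velocities_and_flows",
    "so2_from_intensities",
    "classify_flow",
    "functional_capillary_density",
    "group_stats",
]

RBC_VOLUME_UM3 = units.RBC_VOLUME_UM3

#: frames below this |velocity| (mm/s) count as stationary for classification
STATIONARY_VELOCITY_MM_S = 0.005


@dataclass
class CapillaryRecord:
    """One capillary's measured inputs in one condition."""

    capillary_id: str
    animal_id: str
    condition: str                      # "baseline" or "clamp"
    velocity_mm_s: np.ndarray           # frame-wise RBC velocity, >= 0
    lineal_density_per_mm: np.ndarray   # frame-wise
    diameter_um: float
    segment_length_um: float
    field_id: str = ""
    motion_trace_mm_s: np.ndarray | None = None   # signed, for classification
    frame_rate_hz: float = 21.0
    intensities: dict | None = None     # {"I_O_442":..,"I_RBC_442":..,"I_O_454":..,"I_RBC_454":..}

    def __post_init__(self) -> None:
        self.velocity_mm_s = np.atleast_1d(np.asarray(self.velocity_mm_s, dtype=float))
        self.lineal_density_per_mm = np.atleast_1d(np.asarray(self.lineal_density_per_mm, dtype=float))
        if (self.velocity_mm_s < 0).any():
            raise ValueError("frame-wise RBC velocities must be >= 0 (encode reversals in the motion trace)")
        if (self.lineal_density_per_mm < 0).any():
            raise ValueError("lineal densities must be >= 0")
        if not (2.0 < self.diameter_um < 12.0):
            raise ValueError(f"capillary diameter {self.diameter_um} um outside the plausible (2, 12) range")


@dataclass
class DerivedHemodynamics:
    """All quantities derived from one CapillaryRecord."""

    capillary_id: str
    condition: str
    mean_velocity_mm_s: float
    supply_rate_rbc_s: float
    tube_hct: float
    discharge_hct: float
    blood_velocity_mm_s: float
    plasma_velocity_mm_s: float
    q_rbc_pl_s: float
    q_plasma_pl_s: float
    q_blood_pl_s: float
    so2: float | None = None
    flow_class: str | None = None
    animal_id: str = ""
    field_id: str = ""


def tube_hematocrit(lineal_density_per_mm: np.ndarray | float, D: float,
                    rbc_volume_um3: float = RBC_VOLUME_UM3) -> float:
    """Tube hematocrit from lineal density (RBC/mm) and diameter (um).

    HT = LD * V_RBC / (pi (D/2)^2 * 1000 um^3 per mm of vessel), evaluated
    per frame and then time-averaged. Values above 1 flag an invalid record.
    """
    if D <= 0:
        raise ValueError("diameter must be positive")
    ld = np.atleast_1d(np.asarray(lineal_density_per_mm, dtype=float))
    ht = ld * rbc_volume_um3 / (math.pi * (D / 2.0) ** 2 * 1000.0)
    out = float(ht.mean())
    if out > 1.0:
        raise ValueError(f"tube hematocrit {out:.3f} > 1: invalid record")
    return out


def supply_rate(velocity_mm_s: np.ndarray | float, lineal_density_per_mm: np.ndarray | float) -> float:
    """Time-averaged RBC supply rate (RBC/s): mean of frame-wise v x LD."""
    v = np.atleast_1d(np.asarray(velocity_mm_s, dtype=float))
    ld = np.atleast_1d(np.asarray(lineal_density_per_mm, dtype=float))
    return float(np.mean(v * ld))


def derive_velocities_and_flows(record: CapillaryRecord,
                                rheo: RheologyParams = DEFAULT_RHEOLOGY) -> DerivedHemodynamics:
    """Full derivation chain for one capillary.

    HD inverts the Fahraeus relation at the capillary diameter; blood
    velocity is (HT/HD) x RBC velocity (RBCs outrun bulk blood); plasma
    velocity solves v_blood = HT v_RBC + (1-HT) v_plasma; flows assume a
    circular cross-section. Q_RBC uses the supply rate and the 65 um^3 rat
    RBC volume; Q_plasma = Q_blood - Q_RBC.
    """
    ht = tube_hematocrit(record.lineal_density_per_mm, record.diameter_um)
    sr = supply_rate(record.velocity_mm_s, record.lineal_density_per_mm)
    v_rbc = float(record.velocity_mm_s.mean())
    hd = discharge_hct(record.diameter_um, ht, rheo)
    if hd > 0:
        v_blood = ht / hd * v_rbc
    else:
        v_blood = v_rbc
    v_plasma = (v_blood - ht * v_rbc) / (1.0 - ht) if ht < 1.0 else v_blood
    area_um2 = math.pi * (record.diameter_um / 2.0) ** 2
    q_rbc = sr * RBC_VOLUME_UM3 * units.UM3_TO_PL                       # pL/s
    q_blood = v_blood * 1000.0 * area_um2 * units.UM3_TO_PL             # mm/s -> um/s
    q_plasma = q_blood - q_rbc
    flow_class = None
    if record.motion_trace_mm_s is not None:
        flow_class = classify_flow(record.motion_trace_mm_s, record.frame_rate_hz)
    so2 = None
    if record.intensities is not None:
        so2 = so2_from_intensities(
            record.intensities["I_O_442"], record.intensities["I_RBC_442"],
            record.intensities["I_O_454"], record.intensities["I_RBC_454"])
    return DerivedHemodynamics(
        capillary_id=record.capillary_id, condition=record.condition,
        animal_id=record.animal_id, field_id=record.field_id,
        mean_velocity_mm_s=v_rbc, supply_rate_rbc_s=sr,
        tube_hct=ht, discharge_hct=hd,
        blood_velocity_mm_s=v_blood, plasma_velocity_mm_s=v_plasma,
        q_rbc_pl_s=q_rbc, q_plasma_pl_s=q_plasma, q_blood_pl_s=q_blood,
        so2=so2, flow_class=flow_class)


def so2_from_intensities(I_O_442: float, I_RBC_442: float, I_O_454: float, I_RBC_454: float,
                         calibration: tuple[float, float] = (1.0, 0.0)) -> float:
    """Hemoglobin O2 saturation from two-wavelength optical densities.

    OD = log10(I_O / I_RBC) at 442 nm (oxygen-sensitive) and 454 nm
    (isosbestic); SO2 = clamp(a * OD442/OD454 + b, 0, 1) with the affine
    in vivo calibration ``(a, b)``.
    """
    for name, v in (("I_O_442", I_O_442), ("I_RBC_442", I_RBC_442),
                    ("I_O_454", I_O_454), ("I_RBC_454", I_RBC_454)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    od442 = math.log10(I_O_442 / I_RBC_442)
    od454 = math.log10(I_O_454 / I_RBC_454)
    if od454 == 0.0:
        raise ValueError("reference optical density is zero: SO2 undefined, exclude record")
    a, b = calibration
    return min(1.0, max(0.0, a * od442 / od454 + b))


def classify_flow(motion_trace_mm_s: np.ndarray, frame_rate_hz: float = 21.0,
                  stationary_threshold_mm_s: float = STATIONARY_VELOCITY_MM_S) -> str:
    """Classify a 30-s signed velocity trace.

    * ``stopped``: stationary for the full 30 s;
    * ``intermittent``: at least one stationary spell shorter than 30 s, or
      at least one direction reversal;
    * ``continuous`` otherwise.

    Raises on traces shorter than 30 s.
    """
    v = np.asarray(motion_trace_mm_s, dtype=float)
    if v.size / frame_rate_hz < 30.0 - 1e-9:
        raise ValueError(f"trace covers {v.size / frame_rate_hz:.1f} s; need >= 30 s")
    stationary = np.abs(v) <= stationary_threshold_mm_s
    if stationary.all():
        return "stopped"
    moving = v[~stationary]
    reversed_ = (moving > 0).any() and (moving < 0).any()
    if stationary.any() or reversed_:
        return "intermittent"
    return "continuous"


def functional_capillary_density(counts_per_line: list[int] | np.ndarray,
                                 line_length_mm: float) -> float:
    """Capillaries with RBC flow per mm of reference test line."""
    if line_length_mm <= 0:
        raise ValueError("line length must be positive")
    counts = np.asarray(counts_per_line, dtype=float)
    return float(counts.sum() / (line_length_mm * counts.size))


_PAIRED_VARS = ["mean_velocity_mm_s", "blood_velocity_mm_s", "plasma_velocity_mm_s",
                "supply_rate_rbc_s", "tube_hct", "discharge_hct",
                "q_rbc_pl_s", "q_plasma_pl_s", "q_blood_pl_s"]


def group_stats(derived: pd.DataFrame) -> dict:
    """Study-level statistics on paired baseline/clamp derived records.

    ``derived`` needs one row per capillary x condition with a
    ``capillary_id`` and ``condition`` in {"baseline", "clamp"} and the
    derived hemodynamic columns.

    Returns paired t tests per variable, mean percent changes, and the
    capillary-level linear regressions of percent change in RBC flow and in
    plasma flow on the corresponding baseline flow (slope, intercept, r^2,
    p, runs-test p on residuals).
    """
    base = derived[derived["condition"] == "baseline"].set_index("capillary_id")
    clamp = derived[derived["condition"] == "clamp"].set_index("capillary_id")
    common = base.index.intersection(clamp.index)
    if len(common) < 2:
        raise ValueError("need at least 2 paired capillaries")
    base, clamp = base.loc[common], clamp.loc[common]

    paired = {}
    for var in _PAIRED_VARS:
        if var not in base.columns:
            continue
        b, c = base[var].to_numpy(dtype=float), clamp[var].to_numpy(dtype=float)
        if np.allclose(b, c):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(c, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (c - b) / b
        paired[var] = {
            "t": float(t), "p": float(p), "n": len(b),
            "mean_baseline": float(b.mean()), "mean_clamp": float(c.mean()),
            "mean_pct_change": float(np.nanmean(pct[np.isfinite(pct)])),
        }

    def _regression(flow_var: str) -> dict:
        b = base[flow_var].to_numpy(dtype=float)
        c = clamp[flow_var].to_numpy(dtype=float)
        keep = b > 0
        pct = 100.0 * (c[keep] - b[keep]) / b[keep]
        X = sm.add_constant(b[keep])
        fit = sm.OLS(pct, X).fit()
        resid = fit.resid
        runs_p = float(runstest_1samp(resid, correction=False)[1]) if len(resid) > 3 else float("nan")
        return {
            "slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared), "slope_p": float(fit.pvalues[1]),
            "runs_test_p": runs_p, "n": int(keep.sum()),
        }

    out = {"paired_t": paired, "n_pairs": len(common)}
    if "q_rbc_pl_s" in base.columns:
        out["rbc_flow_pct_change_regression"] = _regression("q_rbc_pl_s")
    if "q_plasma_pl_s" in base.columns:
        out["plasma_flow_pct_change_regression"] = _regression("q_plasma_pl_s")
    return out


def derived_to_frame(items: list[DerivedHemodynamics]) -> pd.DataFrame:
    """Stack DerivedHemodynamics records into a tidy DataFrame."""
    return pd.DataFrame([d.__dict__ for d in items])
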