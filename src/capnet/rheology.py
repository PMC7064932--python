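"""Empirical microvascular constitutive laws.

Three ingredients of two-phase (RBC + plasma) flow in microvessels:

* the *in vivo* apparent relative viscosity of blood as a function of vessel
  diameter and discharge hematocrit (Pries-type in vivo formulation);
* the Fahraeus effect relating tube (volume-averaged) hematocrit HT to
  discharge (flow-averaged) hematocrit HD, with a numerical inverse; and
* the phase-separation ("plasma skimming") law giving the fraction of the
  RBC flux entering a daughter branch of a diverging bifurcation as a
  non-linear function of the fractional blood flow into that branch.

All diameters are in micrometers; hematocrits are fractions in [0, 1].
Constants live in :class:`RheologyParams` so alternative published variants
can be swapped without touching the law implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from scipy.optimize import brentq

__all__ = [
    "RheologyParams",
    "relative_viscosity",
    "tube_hct",
    "discharge_hct",
    "rbc_split",
]


@dataclass(frozen=True)
class RheologyParams:
    """Constants of the empirical laws.

    Attributes
    ----------
    plasma_viscosity_mPa_s:
        Reference plasma viscosity (mPa*s); relative viscosities are
        multiplied by this to obtain the apparent blood viscosity.
    fahraeus_a, fahraeus_b, fahraeus_c, fahraeus_d:
        Constants of the Fahraeus relation
        ``HT/HD = HD + (1 - HD) * (1 + a*exp(b*D) - c*exp(d*D))``.
    ps_a_coeff, ps_b_coeff, ps_x0_coeff:
        Constants of the in vivo phase-separation law: the intercept A,
        slope B, and zero-flux cutoff X0 coefficients (all scaled by the
        feed diameter, the latter two also by ``1 - HD``).
    variant:
        Human-readable name of the adopted published formulation; recorded
        in run metadata for provenance.
    """

    plasma_viscosity_mPa_s: float = 1.2
    # Fahraeus relation HT/HD = HD + (1-HD)(1 + 1.7 e^{-0.415 D} - 0.6 e^{-0.011 D})
    fahraeus_a: float = 1.7
    fahraeus_b: float = -0.415
    fahraeus_c: float = 0.6
    fahraeus_d: float = -0.011
    # phase separation, in vivo form:
    #   A = -ps_a_coeff * [(Da^2-Db^2)/(Da^2+Db^2)] * (1-HD) / Df
    #   B = 1 + ps_b_coeff * (1-HD) / Df
    #   X0 = ps_x0_coeff * (1-HD) / Df
    ps_a_coeff: float = 13.29
    ps_b_coeff: float = 6.98
    ps_x0_coeff: float = 0.964
    variant: str = "Pries in vivo viscosity + in vivo phase separation"

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_RHEOLOGY = RheologyParams()


def _check_diameter(D: float, minimum: float = 0.0) -> None:
    if not math.isfinite(D) or D <= minimum:
        raise ValueError(f"diameter must be a finite value > {minimum} um, got {D}")


def relative_viscosity(D: float, HD: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Apparent in vivo relative viscosity of blood.

    Parameters
    ----------
    D:
        Vessel inner diameter (um); must exceed 3 um (below this the law,
        which folds in an effective endothelial surface layer through the
        ``D - 1.1`` terms, is outside its fitted domain).
    HD:
        Discharge hematocrit, 0 <= HD < 1.

    Returns
    -------
    Viscosity relative to plasma (dimensionless, >= the cell-free value).
    """
    _check_diameter(D, minimum=3.0)
    if not (0.0 <= HD < 1.0):
        raise ValueError(f"discharge hematocrit must be in [0, 1), got {HD}")
    # viscosity at HD = 0.45 in a glass tube corrected in vivo
    eta45 = 6.0 * math.exp(-0.085 * D) + 3.2 - 2.44 * math.exp(-0.06 * D**0.645)
    dpow = D**12 / (D**12 + 10.0**11)  # smooth switch around D ~ 8 um
    C = (0.8 + math.exp(-0.075 * D)) * (-1.0 + dpow) + dpow
    wall = (D / (D - 1.1)) ** 2
    if HD == 0.0:
        return wall
    shape = ((1.0 - HD) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    return (1.0 + (eta45 - 1.0) * shape * wall) * wall


def _fahraeus_ratio(D: float, HD: float, p: RheologyParams) -> float:
    """HT/HD as a function of D (um) and HD."""
    shape = 1.0 + p.fahraeus_a * math.exp(p.fahraeus_b * D) - p.fahraeus_c * math.exp(p.fahraeus_d * D)
    return HD + (1.0 - HD) * shape


def tube_hct(D: float, HD: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Tube (volume-averaged) hematocrit from discharge hematocrit.

    RBCs travel nearer the centerline and hence faster than bulk blood, so
    the tube hematocrit is below the discharge hematocrit in microvessels
    (Fahraeus effect); the ratio approaches 1 as D grows.
    """
    _check_diameter(D)
    if not (0.0 <= HD <= 1.0):
        raise ValueError(f"discharge hematocrit must be in [0, 1], got {HD}")
    return HD * _fahraeus_ratio(D, HD, params)


def discharge_hct(D: float, HT: float, params: RheologyParams = DEFAULT_RHEOLOGY) -> float:
    """Invert the Fahraeus relation: discharge hematocrit from tube hematocrit.

    Uses bracketed root finding on the monotone map HD -> tube_hct(D, HD);
    tolerance 1e-12 in HD (well below the documented 1e-10 contract).

    Raises
    ------
    ValueError
        If ``HT`` exceeds the largest tube hematocrit attainable at this
        diameter (i.e. ``tube_hct(D, 1) == 1``... any HT > 1) or is negative.
    """
    _check_diameter(D)
    if HT < 0.0 or HT > 1.0:
        raise ValueError(f"tube hematocrit {HT} not attainable at D={D} um")
    if HT == 0.0:
        return 0.0
    if HT == 1.0:
        return 1.0
    f = lambda hd: tube_hct(D, hd, params) - HT
    return float(brentq(f, HT, 1.0, xtol=1e-12, rtol=8.9e-16))


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def rbc_split(
    FQB: float,
    Df: float,
    Da: float,
    Db: float,
    HD_feed: float,
    params: RheologyParams = DEFAULT_RHEOLOGY,
    *,
    x0_scale: float = 1.0,
    slope_scale: float = 1.0,
    x0_value: float | None = None,
) -> float:
    """Fractional RBC flux into daughter branch *a* of a diverging bifurcation.

    Parameters
    ----------
    FQB:
        Fraction of the feed *blood* flow entering daughter a.
    Df, Da, Db:
        Feed and daughter diameters (um).
    HD_feed:
        Discharge hematocrit of the feed vessel.
    x0_scale, slope_scale, x0_value:
        Gains on the zero-flux cutoff X0 and on the logit slope B, or a
        fixed cutoff overriding the diameter/hematocrit-dependent one. The
        RBC law uses the defaults; the microbubble law reuses this function
        with a larger fixed cutoff and steeper slope in small vessels.

    Returns
    -------
    FQE in [0, 1]: fraction of the feed RBC flux entering daughter a.
    Exactly 0 below the cutoff X0 and exactly 1 above 1 - X0.
    """
    for name, d in (("Df", Df), ("Da", Da), ("Db", Db)):
        if not math.isfinite(d) or d <= 0:
            raise ValueError(f"{name} must be positive, got {d}")
    if not (0.0 <= FQB <= 1.0):
        raise ValueError(f"fractional blood flow must be in [0, 1], got {FQB}")
    if not (0.0 <= HD_feed < 1.0):
        raise ValueError(f"feed hematocrit must be in [0, 1), got {HD_feed}")

    X0 = params.ps_x0_coeff * (1.0 - HD_feed) / Df * x0_scale if x0_value is None else x0_value
    # a cutoff at or beyond 0.5 would discard flux from both daughters
    X0 = min(X0, 0.499)
    if FQB <= X0:
        return 0.0
    if FQB >= 1.0 - X0:
        return 1.0
    da2, db2 = Da * Da, Db * Db
    A = -params.ps_a_coeff * ((da2 - db2) / (da2 + db2)) * (1.0 - HD_feed) / Df
    B = (1.0 + params.ps_b_coeff * (1.0 - HD_feed) / Df) * slope_scale
    x = (FQB - X0) / (1.0 - 2.0 * X0)
    logit_fqe = A + B * _logit(x)
    return 1.0 / (1.0 + math.exp(-logit_fqe))
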