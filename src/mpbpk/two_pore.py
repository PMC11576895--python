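"""Size-dependent transcapillary transport (two-pore formalism) and renal sieving.

Capillary walls are modelled as two populations of cylindrical pores: small
pores carrying most of the hydraulic conductance and a sparse set of large
pores.  For a solute of Stokes radius ``a_e`` in a pore of radius ``r``,
``lambda = a_e / r`` sets a steric partition coefficient ``(1 - lambda)^2``,
a hindered-diffusion factor (Renkin polynomial) and a pore reflection
coefficient.  Convection and diffusion through each pore class combine in
the Patlak flux expression; the lymph flow of each lumped tissue closes the
fluid balance.  Renal elimination uses a glomerular sieving coefficient
``theta(a_e)`` multiplying GFR, fitted as a logistic curve to a packaged
sieving table.

All closed forms here are classical two-pore results; nothing in this
module is fitted to pharmacokinetic data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoreGeometry",
    "TwoPoreParams",
    "SievingCurve",
    "hindrance_and_reflection",
    "two_pore_params",
    "transcapillary_flux",
    "fit_sieving_curve",
    "load_sieving_curve",
    "sieving_coefficient",
    "renal_clearance",
    "free_diffusion_coefficient",
]

# Defaults of the two-pore literature: small/large pore radii (nm) and the
# fractional hydraulic conductance of the large pores.
R_SMALL_NM = 4.44
R_LARGE_NM = 22.85
ALPHA_LARGE = 0.042


@dataclass(frozen=True)
class PoreGeometry:
    """Pore radii, conductance split and exchange-area scale of one tissue.

    ``a_dx_per_lymph_cm`` converts the tissue lymph flow (L/h) into a total
    pore area / diffusion-path-length ``A0/dx`` (cm); it sets the absolute
    scale of the permeability-surface products.  ``j_iso_frac`` scales the
    isogravimetric circular fluid flow as a fraction of lymph flow.
    """

    r_small_nm: float = R_SMALL_NM
    r_large_nm: float = R_LARGE_NM
    alpha_large: float = ALPHA_LARGE
    a_dx_per_lymph_cm: float = 2.0e6
    j_iso_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (self.r_small_nm > 0 and self.r_large_nm > 0):
            raise ValueError("pore radii must be > 0")
        if not 0 < self.alpha_large < 1:
            raise ValueError("alpha_large must lie in (0, 1)")
        if not self.a_dx_per_lymph_cm > 0:
            raise ValueError("degenerate geometry: zero exchange surface area")
        if not 0 <= self.j_iso_frac < 1 - self.alpha_large:
            raise ValueError("j_iso_frac must keep small-pore flow non-negative")

    @property
    def alpha_small(self) -> float:
        return 1.0 - self.alpha_large


@dataclass(frozen=True)
class TwoPoreParams:
    """Resolved per-tissue transport parameters for one solute size.

    Per pore class: reflection coefficient ``sigma``, permeability-surface
    product ``PS`` (L/h), fluid flow ``J`` (L/h) and Peclet number ``Pe``.
    ``sigma_eff`` is the conductance-weighted effective vascular reflection
    coefficient.
    """

    a_e_nm: float
    sigma_small: float
    sigma_large: float
    PS_small: float
    PS_large: float
    J_small: float
    J_large: float
    Pe_small: float
    Pe_large: float
    J_iso: float
    sigma_eff: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def hindrance_and_reflection(a_e_nm: float, r_pore_nm: float) -> dict:
    """Steric partition, diffusive hindrance and reflection coefficient of one pore.

    Returns ``{"partition", "diffusive_hindrance", "sigma_pore"}`` for
    ``lambda = a_e/r``.  Partition is ``(1-lambda)^2``; diffusive hindrance
    multiplies the Renkin centerline polynomial; the reflection coefficient
    is ``1 - W`` with convective hindrance
    ``W = phi (2 - phi)(1 - lambda^2/3)``.  For ``lambda >= 1`` the solute
    is sterically excluded: all transport factors are 0 and sigma is 1.
    """
    if a_e_nm < 0:
        raise ValueError(f"Stokes radius must be >= 0, got {a_e_nm!r}")
    if not r_pore_nm > 0:
        raise ValueError(f"pore radius must be > 0, got {r_pore_nm!r}")
    lam = a_e_nm / r_pore_nm
    if lam >= 1.0:
        return {"partition": 0.0, "diffusive_hindrance": 0.0, "sigma_pore": 1.0}
    phi = (1.0 - lam) ** 2
    renkin = 1.0 - 2.1044 * lam + 2.089 * lam**3 - 0.948 * lam**5
    H = max(phi * renkin, 0.0)
    W = phi * (2.0 - phi) * (1.0 - lam**2 / 3.0)
    sigma = min(max(1.0 - W, 0.0), 1.0)
    return {"partition": phi, "diffusive_hindrance": H, "sigma_pore": sigma}


def free_diffusion_coefficient(a_e_nm: float) -> float:
    """Stokes-Einstein free diffusion coefficient in plasma water at 37 C (cm^2/h)."""
    if not a_e_nm > 0:
        raise ValueError("Stokes radius must be > 0")
    # kT/(6 pi eta a) with eta = 6.9e-4 Pa s, T = 310 K -> 0.0118/a_nm cm^2/h
    return 0.0118 / a_e_nm


def two_pore_params(
    a_e_nm: float, L_i_L_per_h: float, geometry: PoreGeometry | None = None
) -> TwoPoreParams:
    """Resolve the two-pore transport parameter set for one tissue and solute.

    Fluid balance: the net transcapillary fluid flux equals the tissue lymph
    flow, split as ``J_large = alpha_large L + J_iso`` and ``J_small =
    alpha_small L - J_iso`` (the isogravimetric circular flow recirculates
    outward through large pores and back through small ones).  ``Pe_k =
    J_k (1 - sigma_k) / PS_k`` and ``sigma_eff = alpha_s sigma_s +
    alpha_l sigma_l``.
    """
    geometry = geometry or PoreGeometry()
    if not a_e_nm > 0:
        raise ValueError("Stokes radius must be > 0")
    if not L_i_L_per_h > 0:
        raise ValueError("lymph flow must be > 0")
    hs = hindrance_and_reflection(a_e_nm, geometry.r_small_nm)
    hl = hindrance_and_reflection(a_e_nm, geometry.r_large_nm)
    D = free_diffusion_coefficient(a_e_nm)  # cm^2/h
    # Split A0/dx between classes in proportion to alpha_k / r_k^2
    # (Poiseuille: hydraulic conductance per class ~ (A/dx) r^2).
    w_small = geometry.alpha_small / geometry.r_small_nm**2
    w_large = geometry.alpha_large / geometry.r_large_nm**2
    a_dx_total = geometry.a_dx_per_lymph_cm * L_i_L_per_h  # cm
    a_dx_small = a_dx_total * w_small / (w_small + w_large)
    a_dx_large = a_dx_total * w_large / (w_small + w_large)
    # cm^3/h -> L/h
    PS_small = a_dx_small * D * hs["diffusive_hindrance"] * 1e-3
    PS_large = a_dx_large * D * hl["diffusive_hindrance"] * 1e-3
    J_iso = geometry.j_iso_frac * L_i_L_per_h
    J_large = geometry.alpha_large * L_i_L_per_h + J_iso
    J_small = geometry.alpha_small * L_i_L_per_h - J_iso
    Pe_small = J_small * (1.0 - hs["sigma_pore"]) / PS_small if PS_small > 0 else math.inf
    Pe_large = J_large * (1.0 - hl["sigma_pore"]) / PS_large if PS_large > 0 else math.inf
    sigma_eff = geometry.alpha_small * hs["sigma_pore"] + geometry.alpha_large * hl["sigma_pore"]
    return TwoPoreParams(
        a_e_nm=a_e_nm,
        sigma_small=hs["sigma_pore"],
        sigma_large=hl["sigma_pore"],
        PS_small=PS_small,
        PS_large=PS_large,
        J_small=J_small,
        J_large=J_large,
        Pe_small=Pe_small,
        Pe_large=Pe_large,
        J_iso=J_iso,
        sigma_eff=sigma_eff,
    )


def _patlak(C_v: float, C_is: float, J1s: float, Pe: float, PS: float) -> float:
    """One pore class of the Patlak convection-diffusion flux (nmol/h)."""
    if J1s == 0.0:
        return PS * (C_v - C_is)
    if math.isinf(Pe):
        return J1s * C_v if Pe > 0 else J1s * C_is
    if abs(Pe) < 1e-10:
        return PS * (C_v - C_is)
    em = math.exp(-Pe)
    return J1s * (C_v - C_is * em) / (1.0 - em)


def transcapillary_flux(C_v_nM: float, C_is_nM: float, p: TwoPoreParams) -> float:
    """Net vascular -> interstitial solute flux (nmol/h) summed over pore classes.

    Each class follows the Patlak form ``J(1-sigma)(C_v - C_is e^{-Pe}) /
    (1 - e^{-Pe})``; the Pe -> 0 limit is pure diffusion ``PS (C_v - C_is)``
    and is evaluated analytically, never by division.
    """
    if C_v_nM < 0 or C_is_nM < 0:
        raise ValueError("concentrations must be >= 0")
    total = 0.0
    for sig, PS, J, Pe in (
        (p.sigma_small, p.PS_small, p.J_small, p.Pe_small),
        (p.sigma_large, p.PS_large, p.J_large, p.Pe_large),
    ):
        total += _patlak(C_v_nM, C_is_nM, J * (1.0 - sig), Pe, PS)
    return total


# ---------------------------------------------------------------------------
# Glomerular sieving
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SievingCurve:
    """Logistic sieving coefficient theta(a_e) = 1 / (1 + exp((a_e - a0)/w))."""

    a0_nm: float
    width_nm: float

    def __post_init__(self) -> None:
        if not self.width_nm > 0:
            raise ValueError("sieving curve width must be > 0")

    def __call__(self, a_e_nm: float) -> float:
        if not a_e_nm > 0:
            raise ValueError("Stokes radius must be > 0")
        z = (a_e_nm - self.a0_nm) / self.width_nm
        return 1.0 / (1.0 + math.exp(min(z, 700.0)))


def fit_sieving_curve(table: pd.DataFrame) -> SievingCurve:
    """Fit the logistic theta(a_e) to a sieving table (columns a_e_nm, theta).

    The logit of theta is linear in a_e, so the fit is an ordinary least
    squares line in logit space (rows with theta at 0 or 1 are dropped).
    """
    if not {"a_e_nm", "theta"}.issubset(table.columns):
        raise ValueError("sieving table needs columns a_e_nm, theta")
    t = table[(table["theta"] > 0) & (table["theta"] < 1)]
    if len(t) < 2:
        raise ValueError("need at least two interior sieving points to fit")
    a = t["a_e_nm"].to_numpy(float)
    logit = np.log(t["theta"].to_numpy(float) / (1.0 - t["theta"].to_numpy(float)))
    slope, intercept = np.polyfit(a, logit, 1)
    if slope >= 0:
        raise ValueError("sieving data must decrease with Stokes radius")
    width = -1.0 / slope
    a0 = intercept * width
    return SievingCurve(a0_nm=a0, width_nm=width)


def load_sieving_curve() -> SievingCurve:
    """Fit the sieving curve to the packaged synthetic sieving table."""
    text = resources.files("mpbpk.data").joinpath("sieving_synthetic.csv").read_text()
    return fit_sieving_curve(pd.read_csv(io.StringIO(text), comment="#"))


def sieving_coefficient(a_e_nm: float, curve: SievingCurve | None = None) -> float:
    """Glomerular sieving coefficient theta in [0, 1], non-increasing in a_e."""
    if curve is None:
        raise ValueError("sieving curve parameters are required")
    return curve(a_e_nm)


def renal_clearance(GFR_L_per_h: float, theta: float) -> float:
    """Size-based renal clearance (L/h) = GFR * theta."""
    if not GFR_L_per_h > 0:
        raise ValueError("GFR must be > 0")
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta!r}")
    return GFR_L_per_h * theta
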