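"""Empirical relations between net surface charge and charge-sensitive PK parameters.

Three parameters carry the charge dependence of antibody disposition:

* ``K_p`` — the fraction of interstitial volume accessible to the antibody.
  Both positive and negative variants are excluded from part of the matrix,
  so ``K_p(z)`` is a concave quadratic pinned at ``K_p(0) = 1``.
* ``K_D,NSB`` — the equilibrium dissociation constant of non-specific
  binding to negatively charged membrane constituents; positive charge
  means tighter binding, so the curve decreases with z.
* ``S_pino`` — a multiplicative scaling of the pinocytosis rate; positive
  charge enhances fluid-phase uptake in leaky-tissue endothelium only.

All three curves are anchored at the measured charge variants z = -8, 0, +5
and are valid over z in [-10, +10]; outside that range the charge is clamped
with a logged warning.  ``k_on,NSB`` is never free: it equals the antibody's
FcRn association constant ``k1on`` wherever non-specific binding is active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ANCHORS",
    "ChargeRelations",
    "fit_charge_relations",
    "default_charge_relations",
]

Z_MIN, Z_MAX = -10.0, 10.0

#: (z, K_p, K_D_NSB [nM], S_pino_leaky) at the three measured charge variants.
DEFAULT_ANCHORS = ((-8.0, 0.62, 16.22, 1.0), (0.0, 1.0, 8.35, 1.0), (5.0, 0.8, 1.21, 2.99))


def _clamp(z: float) -> float:
    if z < Z_MIN or z > Z_MAX:
        logger.warning("net charge %.3g outside validity range [%g, %g]; clamping", z, Z_MIN, Z_MAX)
        return min(max(z, Z_MIN), Z_MAX)
    return z


@dataclass(frozen=True)
class ChargeRelations:
    """Fitted charge -> (K_p, K_D_NSB, S_pino) relations.

    ``kp_coeffs`` are the quadratic coefficients (a, b, c) of
    ``K_p(z) = a z^2 + b z + c`` with c constrained to 1.
    ``kdnsb_params`` are (L, U, z0, w) of the log-space logistic
    ``ln K_D(z) = L - U / (1 + exp(-(z - z0)/w))`` — positive and strictly
    decreasing for U > 0, unlike a raw quadratic which would cross zero
    inside the validity range.  ``spino_slope`` is the leaky-tissue linear
    gain per unit positive charge; tight tissue and the plasma nested
    endosome always use 1.
    """

    kp_coeffs: tuple[float, float, float]
    kdnsb_params: tuple[float, float, float, float]
    spino_slope: float
    anchors: tuple = field(default=DEFAULT_ANCHORS)

    def kp(self, z: float) -> float:
        z = _clamp(z)
        a, b, c = self.kp_coeffs
        # the interpolating quadratic can poke marginally above 1 between
        # the negative anchor and zero; K_p is a volume fraction, so cap it
        return min(a * z * z + b * z + c, 1.0)

    def kdnsb(self, z: float) -> float:
        z = _clamp(z)
        L, U, z0, w = self.kdnsb_params
        return math.exp(L - U / (1.0 + math.exp(-(z - z0) / w)))

    def spino(self, z: float, tissue: str) -> float:
        if tissue not in ("tight", "leaky"):
            raise ValueError(f"unknown tissue label {tissue!r} (expected 'tight' or 'leaky')")
        z = _clamp(z)
        if tissue == "tight" or z <= 0:
            return 1.0
        return 1.0 + self.spino_slope * z


def _fit_kp(anchors: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Least-squares quadratic through (z, K_p) anchors with intercept pinned to 1."""
    z = np.array([a[0] for a in anchors])
    kp = np.array([a[1] for a in anchors])
    nz = z != 0
    A = np.column_stack([z[nz] ** 2, z[nz]])
    ab, *_ = np.linalg.lstsq(A, kp[nz] - 1.0, rcond=None)
    return (float(ab[0]), float(ab[1]), 1.0)


def _fit_kdnsb(anchors: list[tuple[float, float]], width: float = 2.0) -> tuple:
    """Solve the log-logistic (L, U, z0) exactly through three (z, K_D) anchors.

    With more than three anchors the extra points enter a least-squares
    refinement; non-monotone anchors are warned about and fitted anyway
    (the functional form itself enforces monotonicity).
    """
    zs = np.array([a[0] for a in anchors], float)
    ys = np.log(np.array([a[1] for a in anchors], float))
    order = np.argsort(zs)
    zs, ys = zs[order], ys[order]
    if np.any(np.diff(ys) >= 0):
        logger.warning("non-monotone K_D,NSB anchors; fitting a monotone curve through them")

    def sig(z, z0):
        return 1.0 / (1.0 + np.exp(-(z - z0) / width))

    z_lo, z_mid, z_hi = zs[0], zs[len(zs) // 2], zs[-1]
    y_lo, y_mid, y_hi = ys[0], ys[len(zs) // 2], ys[-1]

    def ratio_residual(z0):
        s = sig(np.array([z_lo, z_mid, z_hi]), z0)
        return (y_mid - y_hi) * (s[1] - s[0]) - (y_lo - y_mid) * (s[2] - s[1])

    lo, hi = z_lo - 50.0, z_hi + 50.0
    try:
        z0 = brentq(ratio_residual, lo, hi, xtol=1e-12)
    except ValueError:
        z0 = 0.5 * (z_lo + z_hi)  # degenerate anchors; fall back to midpoint
    s = sig(np.array([z_lo, z_hi]), z0)
    U = (y_lo - y_hi) / (s[1] - s[0])
    L = y_lo + U * s[0]
    return (float(L), float(U), float(z0), float(width))


def fit_charge_relations(anchors=DEFAULT_ANCHORS) -> ChargeRelations:
    """Fit all three charge relations to (z, K_p, K_D_NSB, S_pino) anchor rows.

    Requires at least three anchors including the neutral variant z = 0
    (which pins K_p and S_pino to 1).
    """
    anchors = tuple(tuple(map(float, a)) for a in anchors)
    if len(anchors) < 3:
        raise ValueError(f"need >= 3 charge anchors, got {len(anchors)}")
    if not any(a[0] == 0.0 for a in anchors):
        raise ValueError("anchors must include the neutral variant z = 0")
    kp_coeffs = _fit_kp([(a[0], a[1]) for a in anchors])
    kdnsb_params = _fit_kdnsb([(a[0], a[2]) for a in anchors])
    pos = [(a[0], a[3]) for a in anchors if a[0] > 0 and a[3] > 1.0]
    if pos:
        slope = float(np.mean([(s - 1.0) / z for z, s in pos]))
    else:
        slope = 0.0
    return ChargeRelations(
        kp_coeffs=kp_coeffs, kdnsb_params=kdnsb_params, spino_slope=slope, anchors=anchors
    )


_DEFAULT: ChargeRelations | None = None


def default_charge_relations() -> ChargeRelations:
    """Relations fitted once to the packaged anchor estimates."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = fit_charge_relations(DEFAULT_ANCHORS)
    return _DEFAULT
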