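"""The minimal PBPK ODE system: state layout, fluxes, dosing and observables.

Compartments
------------
Plasma (with a nested endothelial endosome), lymph, and two lumped tissues
(tight = brain+muscle+skin+adipose, leaky = everything else), each split
into vascular, endosomal and interstitial sub-spaces.  All 39 states are
concentrations in nM within their own sub-space volume.

Processes
---------
* plasma <-> tissue vascular exchange by plasma flow, lymph return;
* two-pore transcapillary transport of antibody and soluble complex into a
  charge-scaled accessible interstitial volume ``K_p * V_is``;
* fluid-phase pinocytosis into endosomes (charge-scaled by ``S_pino``),
  pH-6 FcRn binding, recycling back to vascular/interstitial space,
  lysosomal degradation of free antibody, catabolism of antigen species;
* pH-7.4 binding to soluble antigen, membrane antigen (TMDD) and
  negatively charged membrane constituents (non-specific binding, NSB);
  internalized membrane complexes leave the tracked system;
* size-based renal elimination from the leaky vascular space.

Endosomal pH is not a state: acidic-pH kinetics (``k1on/k1off``,
``keon/keoff``) apply inside endosomes, neutral-pH kinetics (``kon/koff``)
everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field
from types import SimpleNamespace

import numpy as np

from .compound import AntibodyDescriptor, TargetDescriptor
from .physiology import SpeciesPhysiology, recycling_clearance
from .two_pore import (
    PoreGeometry,
    SievingCurve,
    TwoPoreParams,
    load_sieving_curve,
    renal_clearance,
    two_pore_params,
)
from .charge import ChargeRelations, default_charge_relations

__all__ = [
    "N_STATES",
    "STATE_NAMES",
    "ModelParams",
    "build_model_params",
    "initial_state",
    "ode_rhs",
    "make_rhs",
    "total_antibody_amount",
    "lumped_tissue_concentration",
    "observed_lumping",
    "PKProfile",
]

# ---------------------------------------------------------------------------
# State layout (39 concentrations, nM)
# ---------------------------------------------------------------------------

A_P, TS_P, ATS_P = 0, 1, 2
A_EP, TS_EP, ATS_EP, F_EP, AF_EP, ATF_EP = 3, 4, 5, 6, 7, 8
A_LY, ATS_LY = 9, 10
# per-tissue block offsets (tight: base 11, leaky: base 25)
_TB = 11
_NT = 14
(oA_V, oTS_V, oATS_V, oTM_V, oATM_V, oARM_V,
 oA_E, oTS_E, oATS_E, oF_E, oAF_E, oATF_E, oA_IS, oATS_IS) = range(_NT)

N_STATES = _TB + 2 * _NT  # 39

_TISSUE_NAMES = ("tight", "leaky")
STATE_NAMES = ["A_p", "Ts_p", "ATs_p", "A_ep", "Ts_ep", "ATs_ep", "F_ep", "AF_ep", "ATF_ep",
               "A_lymph", "ATs_lymph"]
for _t in _TISSUE_NAMES:
    STATE_NAMES += [f"{s}_{_t}" for s in
                    ("A_v", "Ts_v", "ATs_v", "Tm_v", "ATm_v", "ARm_v",
                     "A_e", "Ts_e", "ATs_e", "F_e", "AF_e", "ATF_e", "A_is", "ATs_is")]


def tissue_base(i: int) -> int:
    return _TB + i * _NT


# ---------------------------------------------------------------------------
# Resolved parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Fully resolved rate constants and transport parameters for one simulation.

    Built by :func:`build_model_params`; individual fields can be replaced
    with :meth:`with_overrides` (dependent quantities such as pinocytic
    clearances and antigen synthesis rates are recomputed when the system
    is prepared for integration, so overriding a primitive is always
    consistent).
    """

    physiology: SpeciesPhysiology
    antibody: AntibodyDescriptor
    target: TargetDescriptor | None
    tp_tight: TwoPoreParams
    tp_leaky: TwoPoreParams
    sigma_1: float
    sigma_2: float
    k_up: float = 0.0366        # tissue endosomal uptake rate, 1/h
    k_up_p: float = 0.0366      # plasma nested endosomal uptake rate, 1/h
    k_deg: float = 60.0         # lysosomal degradation of free endosomal mAb, 1/h
    CL_cat: float = 0.0         # catabolic clearance of antigen species per endosome, L/h
    FcRn_total: float = 49800.0  # nM
    R_m_total: float = 0.0      # nM; 0 disables non-specific membrane binding
    K_D_NSB: float = 8.35       # nM
    S_pino_1: float = 1.0
    S_pino_2: float = 1.0
    K_p: float = 1.0
    CL_renal: float = 0.0       # L/h, leaky vascular space only
    f_rec_v: float = 0.5        # recycled fraction routed to the vascular side
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for k in ("k_up", "k_up_p", "k_deg", "CL_cat", "FcRn_total", "R_m_total",
                  "K_D_NSB", "CL_renal"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0, got {getattr(self, k)!r}")
        for k in ("sigma_1", "sigma_2"):
            if not 0.0 <= getattr(self, k) <= 1.0:
                raise ValueError(f"{k} must lie in [0, 1]")
        if not 0.0 <= self.f_rec_v <= 1.0:
            raise ValueError("f_rec_v must lie in [0, 1]")
        if not 0.0 < self.K_p <= 1.0:
            raise ValueError("K_p must lie in (0, 1]")
        if min(self.S_pino_1, self.S_pino_2) < 1.0:
            raise ValueError("S_pino must be >= 1")
        tgt = self.target
        if tgt is not None and tgt.T_s0_nM > 0 and not self.CL_cat > 0:
            raise ValueError("a soluble target requires CL_cat > 0 (endosomal catabolism)")

    # convenience accessors -------------------------------------------------
    @property
    def k_on_NSB(self) -> float:
        """NSB association constant: always tied to the FcRn association constant."""
        return self.antibody.k1on

    @property
    def k_off_NSB(self) -> float:
        return self.K_D_NSB * self.k_on_NSB

    def with_overrides(self, **kwargs) -> "ModelParams":
        """Replace primitives; physiology and target fields are routed through.

        Dependent quantities (pinocytic clearances, synthesis rates, NSB
        off-rate) are recomputed in :meth:`prepare`, so any primitive can
        be overridden consistently, e.g. during fitting or sensitivity
        perturbation.
        """
        phys_keys = {k: kwargs.pop(k) for k in list(kwargs) if hasattr(self.physiology, k)}
        if "FcRn_total_nM" in phys_keys:  # keep the resolved copy in sync
            kwargs.setdefault("FcRn_total", phys_keys["FcRn_total_nM"])
        tgt_keys = {}
        if self.target is not None:
            tgt_fields = set(self.target.__dataclass_fields__)
            tgt_keys = {k: kwargs.pop(k) for k in list(kwargs)
                        if k in tgt_fields and not hasattr(type(self), k)
                        and k not in self.__dataclass_fields__}
        out = self
        if phys_keys:
            out = replace(out, physiology=out.physiology.with_overrides(**phys_keys))
        if tgt_keys:
            out = replace(out, target=replace(out.target, **tgt_keys))
        return replace(out, **kwargs) if kwargs else out

    # -- prepared scalar bundle for the RHS ---------------------------------
    def prepare(self) -> SimpleNamespace:
        ph, ab, tgt = self.physiology, self.antibody, self.target
        V_v = (ph.V_v_tight_L, ph.V_v_leaky_L)
        V_e = (ph.V_e_tight_L, ph.V_e_leaky_L)
        V_is = (ph.V_is_tight_L, ph.V_is_leaky_L)
        Q = (ph.Q_tight_L_per_h, ph.Q_leaky_L_per_h)
        L = (ph.L_tight_L_per_h, ph.L_leaky_L_per_h)
        S_pino = (self.S_pino_1, self.S_pino_2)
        sigma = (self.sigma_1, self.sigma_2)
        CL_up = tuple(S_pino[i] * self.k_up * V_e[i] for i in range(2))
        CL_up_p = self.k_up_p * ph.V_ep_L
        CL_rec = tuple(recycling_clearance(V_e[i], ph.endosomal_transit_time_h) for i in range(2))
        CL_rec_p = recycling_clearance(ph.V_ep_L, ph.endosomal_transit_time_h)

        # Transcapillary flux classes (J*(1-sigma), Pe, PS) per tissue. The
        # two-pore per-class decomposition is used when sigma_i is the derived
        # effective coefficient; a fitted/overridden sigma_i replaces it by the
        # equivalent single-membrane Patlak with the total PS.
        flux_classes = []
        for i, tp in enumerate((self.tp_tight, self.tp_leaky)):
            if sigma[i] == tp.sigma_eff:
                flux_classes.append((
                    (tp.J_small * (1 - tp.sigma_small), tp.Pe_small, tp.PS_small),
                    (tp.J_large * (1 - tp.sigma_large), tp.Pe_large, tp.PS_large),
                ))
            else:
                PS_tot = tp.PS_small + tp.PS_large
                J1s = L[i] * (1 - sigma[i])
                Pe = J1s / PS_tot if PS_tot > 0 else math.inf
                flux_classes.append(((J1s, Pe, PS_tot),))

        if tgt is not None:
            k_el_Ts = tgt.soluble_elimination_rate(ph.V_p_L)
            T_s0, T_m0 = tgt.T_s0_nM, tgt.T_m0_nM
            k_p_Tm, k_int = tgt.k_p_Tm, tgt.k_int
        else:
            k_el_Ts = T_s0 = T_m0 = k_p_Tm = k_int = 0.0
        # Antigen synthesis rates hold the stated baselines as an exact
        # drug-free steady state (elimination + pinocytic loss compensated).
        k_syn_p = T_s0 * (k_el_Ts + CL_up_p / ph.V_p_L)
        k_syn_v = tuple(T_s0 * (k_el_Ts + CL_up[i] / V_v[i]) for i in range(2))
        k_syn_m = T_m0 * k_p_Tm
        kcat_p = self.CL_cat / ph.V_ep_L
        kcat = tuple(self.CL_cat / V_e[i] for i in range(2))

        return SimpleNamespace(
            V_p=ph.V_p_L, V_ly=ph.V_lymph_L, V_ep=ph.V_ep_L,
            V_v=V_v, V_e=V_e, V_is=V_is, V_is_acc=tuple(self.K_p * v for v in V_is),
            Q=Q, L=L, L_tot=ph.L_total_L_per_h, sigma_L=ph.sigma_L,
            flux_classes=flux_classes,
            CL_up=CL_up, CL_up_p=CL_up_p, CL_rec=CL_rec, CL_rec_p=CL_rec_p,
            krec=tuple(CL_rec[i] / V_e[i] for i in range(2)), krec_p=CL_rec_p / ph.V_ep_L,
            k_deg=self.k_deg, kcat=kcat, kcat_p=kcat_p,
            FcRn_total=self.FcRn_total, R_m_total=self.R_m_total,
            k_on_NSB=self.k_on_NSB if self.R_m_total > 0 else 0.0,
            k_off_NSB=self.k_off_NSB,
            k_int_ARm=tuple(S_pino[i] * self.k_up for i in range(2)),
            CL_renal=self.CL_renal, f_rec_v=self.f_rec_v,
            k1on=ab.k1on, k1off=ab.k1off, kon=ab.kon, koff=ab.koff,
            keon=ab.keon, keoff=ab.keoff,
            k_el_Ts=k_el_Ts, T_s0=T_s0, T_m0=T_m0, k_p_Tm=k_p_Tm, k_int=k_int,
            k_syn_p=k_syn_p, k_syn_v=k_syn_v, k_syn_m=k_syn_m,
        )


def build_model_params(
    physiology: SpeciesPhysiology,
    antibody: AntibodyDescriptor,
    target: TargetDescriptor | None = None,
    *,
    charge_relations: ChargeRelations | None = None,
    sieving_curve: SievingCurve | None = None,
    geometry: PoreGeometry | None = None,
    overrides: dict | None = None,
) -> ModelParams:
    """Resolve physiology + compound descriptors into a simulation parameter set.

    Charge enters through the fitted empirical relations (``K_p``,
    ``K_D,NSB``, ``S_pino``); size enters through the two-pore transport
    parameters and the sieving-based renal clearance.  ``overrides`` may
    replace any :class:`ModelParams` field (fitted values, knockout
    settings) or any :class:`SpeciesPhysiology` field (e.g. ``FcRn_total_nM``).
    """
    overrides = dict(overrides or {})
    phys_overrides = {k: overrides.pop(k) for k in list(overrides) if hasattr(physiology, k)}
    if phys_overrides:
        physiology = physiology.with_overrides(**phys_overrides)
    relations = charge_relations or default_charge_relations()
    sieving = sieving_curve or load_sieving_curve()
    z = antibody.net_charge
    a_e = antibody.a_e_nm

    tp1 = two_pore_params(a_e, physiology.L_tight_L_per_h, geometry)
    tp2 = two_pore_params(a_e, physiology.L_leaky_L_per_h, geometry)
    resolved = dict(
        sigma_1=tp1.sigma_eff,
        sigma_2=tp2.sigma_eff,
        FcRn_total=physiology.FcRn_total_nM,
        K_p=relations.kp(z),
        K_D_NSB=relations.kdnsb(z),
        S_pino_1=relations.spino(z, "tight"),
        S_pino_2=relations.spino(z, "leaky"),
        CL_renal=renal_clearance(physiology.GFR_L_per_h, sieving(a_e)),
    )
    if target is not None:
        tgt_fields = set(target.__dataclass_fields__)
        tgt_overrides = {k: overrides.pop(k) for k in list(overrides)
                         if k in tgt_fields and k not in ModelParams.__dataclass_fields__}
        if tgt_overrides:
            target = replace(target, **tgt_overrides)
        if target.CL_cat_L_per_h > 0:
            resolved["CL_cat"] = target.CL_cat_L_per_h
    resolved.update(overrides)
    return ModelParams(
        physiology=physiology, antibody=antibody, target=target,
        tp_tight=tp1, tp_leaky=tp2, **resolved,
    )


# ---------------------------------------------------------------------------
# Initial condition
# ---------------------------------------------------------------------------


def initial_state(params: ModelParams, dose_amount_nmol: float = 0.0) -> np.ndarray:
    """State vector at t=0: IV bolus in plasma, antigens at steady baseline.

    Free FcRn starts at ``FcRn_total`` in every endosome; soluble antigen
    sits at its baseline in plasma and tissue vascular spaces and at the
    consistent uptake/catabolism steady state inside endosomes; membrane
    antigen at its baseline; every complex at zero.
    """
    if dose_amount_nmol < 0:
        raise ValueError(f"dose must be >= 0, got {dose_amount_nmol!r}")
    p = params.prepare()
    y = np.zeros(N_STATES)
    y[A_P] = dose_amount_nmol / p.V_p
    y[F_EP] = p.FcRn_total
    if p.T_s0 > 0:
        y[TS_P] = p.T_s0
        y[TS_EP] = p.CL_up_p * p.T_s0 / params.CL_cat
    for i in range(2):
        b = tissue_base(i)
        y[b + oF_E] = p.FcRn_total
        if p.T_s0 > 0:
            y[b + oTS_V] = p.T_s0
            y[b + oTS_E] = p.CL_up[i] * p.T_s0 / params.CL_cat
        y[b + oTM_V] = p.T_m0
    return y


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def _patlak_classes(C_v: float, C_is: float, classes) -> float:
    flux = 0.0
    for J1s, Pe, PS in classes:
        if Pe == math.inf:
            flux += J1s * C_v
        elif Pe < 1e-10:
            flux += PS * (C_v - C_is)
        else:
            em = math.exp(-Pe)
            flux += J1s * (C_v - C_is * em) / (1.0 - em)
    return flux


def ode_rhs(t: float, y: np.ndarray, params: ModelParams | SimpleNamespace) -> np.ndarray:
    """d(state)/dt for the full system (concentrations, nM/h).

    Accepts either a :class:`ModelParams` (prepared on the fly) or an
    already-prepared namespace from :meth:`ModelParams.prepare`.
    """
    p = params.prepare() if isinstance(params, ModelParams) else params
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ValueError(f"non-finite state at index {bad} ({STATE_NAMES[bad]}) at t={t:g}")
    dy = np.zeros_like(y)

    a_p, ts_p, ats_p = y[A_P], y[TS_P], y[ATS_P]
    a_ep, ts_ep, ats_ep, f_ep, af_ep, atf_ep = y[A_EP:ATF_EP + 1]
    a_ly, ats_ly = y[A_LY], y[ATS_LY]

    # ---- plasma nested endosome (pH 6)
    r1 = p.k1on * a_ep * f_ep - p.k1off * af_ep
    r2 = p.k1on * ats_ep * f_ep - p.k1off * atf_ep
    r3 = p.keon * a_ep * ts_ep - p.keoff * ats_ep
    up = p.CL_up_p / p.V_ep
    dy[A_EP] = up * a_p - p.k_deg * a_ep - r1 - r3
    dy[TS_EP] = up * ts_p - p.kcat_p * ts_ep - r3
    dy[ATS_EP] = up * ats_p - p.kcat_p * ats_ep + r3 - r2
    dy[F_EP] = -r1 - r2 + p.krec_p * (af_ep + atf_ep)
    dy[AF_EP] = r1 - p.krec_p * af_ep
    dy[ATF_EP] = r2 - p.krec_p * atf_ep

    # ---- plasma (pH 7.4); vascular return flows are added in the tissue loop
    rp = p.kon * a_p * ts_p - p.koff * ats_p
    flow_A = -(p.Q[0] + p.Q[1]) * a_p + p.L_tot * a_ly
    flow_ATs = -(p.Q[0] + p.Q[1]) * ats_p + p.L_tot * ats_ly
    flow_Ts = -(p.Q[0] + p.Q[1]) * ts_p
    dy[A_P] = (flow_A - p.CL_up_p * a_p + p.CL_rec_p * af_ep) / p.V_p - rp
    dy[TS_P] = (flow_Ts - p.CL_up_p * ts_p) / p.V_p + p.k_syn_p - p.k_el_Ts * ts_p - rp
    dy[ATS_P] = (flow_ATs - p.CL_up_p * ats_p + p.CL_rec_p * atf_ep) / p.V_p + rp

    # ---- lymph
    dy[A_LY] = -p.L_tot * a_ly / p.V_ly
    dy[ATS_LY] = -p.L_tot * ats_ly / p.V_ly

    for i in range(2):
        b = tissue_base(i)
        (a_v, ts_v, ats_v, tm, atm, arm,
         a_e, ts_e, ats_e, f_e, af_e, atf_e, a_is, ats_is) = y[b:b + _NT]
        V_v, V_e, V_is_acc = p.V_v[i], p.V_e[i], p.V_is_acc[i]
        Q, L = p.Q[i], p.L[i]
        CL_up, CL_rec, krec, kcat = p.CL_up[i], p.CL_rec[i], p.krec[i], p.kcat[i]
        renal = p.CL_renal if i == 1 else 0.0

        # vascular (pH 7.4)
        rv1 = p.kon * a_v * ts_v - p.koff * ats_v
        rv2 = p.kon * a_v * tm - p.koff * atm
        rm_free = p.R_m_total - arm
        rv3 = p.k_on_NSB * a_v * rm_free - p.k_off_NSB * arm
        JA = _patlak_classes(a_v, a_is, p.flux_classes[i])
        JATs = _patlak_classes(ats_v, ats_is, p.flux_classes[i])
        dy[b + oA_V] = ((Q * a_p - (Q - L) * a_v - JA - CL_up * a_v
                         + p.f_rec_v * CL_rec * af_e - renal * a_v) / V_v
                        - rv1 - rv2 - rv3)
        dy[b + oTS_V] = ((Q * ts_p - Q * ts_v - CL_up * ts_v) / V_v
                         + p.k_syn_v[i] - p.k_el_Ts * ts_v - rv1)
        dy[b + oATS_V] = ((Q * ats_p - (Q - L) * ats_v - JATs - CL_up * ats_v
                           + p.f_rec_v * CL_rec * atf_e - renal * ats_v) / V_v + rv1)
        dy[b + oTM_V] = p.k_syn_m - p.k_p_Tm * tm - rv2
        dy[b + oATM_V] = rv2 - p.k_int * atm
        dy[b + oARM_V] = rv3 - p.k_int_ARm[i] * arm

        # endosome (pH 6)
        re1 = p.k1on * a_e * f_e - p.k1off * af_e
        re2 = p.k1on * ats_e * f_e - p.k1off * atf_e
        re3 = p.keon * a_e * ts_e - p.keoff * ats_e
        dy[b + oA_E] = (CL_up * (a_v + a_is)) / V_e - p.k_deg * a_e - re1 - re3
        dy[b + oTS_E] = CL_up * ts_v / V_e - kcat * ts_e - re3
        dy[b + oATS_E] = (CL_up * (ats_v + ats_is)) / V_e - kcat * ats_e + re3 - re2
        dy[b + oF_E] = -re1 - re2 + krec * (af_e + atf_e)
        dy[b + oAF_E] = re1 - krec * af_e
        dy[b + oATF_E] = re2 - krec * atf_e

        # interstitial (accessible volume K_p * V_is)
        drain = L * (1.0 - p.sigma_L)
        dy[b + oA_IS] = (JA + (1 - p.f_rec_v) * CL_rec * af_e
                         - drain * a_is - CL_up * a_is) / V_is_acc
        dy[b + oATS_IS] = (JATs + (1 - p.f_rec_v) * CL_rec * atf_e
                           - drain * ats_is - CL_up * ats_is) / V_is_acc

        # lymph collects interstitial drainage; vascular outflow returns to plasma
        dy[A_LY] += drain * a_is / p.V_ly
        dy[ATS_LY] += drain * ats_is / p.V_ly
        dy[A_P] += (Q - L) * a_v / p.V_p
        dy[ATS_P] += (Q - L) * ats_v / p.V_p
        dy[TS_P] += Q * ts_v / p.V_p

    return dy


def make_rhs(params: ModelParams):
    """Return a prepared ``rhs(t, y)`` closure for the integrator."""
    p = params.prepare()

    def rhs(t, y):
        return ode_rhs(t, y, p)

    return rhs


def total_antibody_amount(y: np.ndarray, params: ModelParams) -> float:
    """Total antibody (free + all bound species) in the tracked system, nmol."""
    p = params.prepare()
    amt = (y[A_P] + y[ATS_P]) * p.V_p
    amt += (y[A_EP] + y[ATS_EP] + y[AF_EP] + y[ATF_EP]) * p.V_ep
    amt += (y[A_LY] + y[ATS_LY]) * p.V_ly
    for i in range(2):
        b = tissue_base(i)
        amt += (y[b + oA_V] + y[b + oATS_V] + y[b + oATM_V] + y[b + oARM_V]) * p.V_v[i]
        amt += (y[b + oA_E] + y[b + oATS_E] + y[b + oAF_E] + y[b + oATF_E]) * p.V_e[i]
        amt += (y[b + oA_IS] + y[b + oATS_IS]) * p.V_is_acc[i]
    return float(amt)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def lumped_tissue_concentration(C_e, C_v, C_is, V_e, V_v, V_is):
    """Total lumped-tissue concentration: volume-weighted mean of sub-spaces.

    Sub-space concentrations are TOTAL antibody (free + bound) per sub-space;
    interstitial concentration is expressed over the full interstitial volume.
    """
    V_e, V_v, V_is = float(V_e), float(V_v), float(V_is)
    if min(V_e, V_v, V_is) <= 0:
        raise ValueError("sub-space volumes must be > 0")
    return (np.asarray(C_e) * V_e + np.asarray(C_v) * V_v + np.asarray(C_is) * V_is) / (
        V_e + V_v + V_is
    )


def observed_lumping(amounts: dict, volumes: dict, lump: list[str]) -> float:
    """Observed lumped concentration: sum of tissue amounts / sum of volumes."""
    for t in lump:
        if t not in amounts:
            raise KeyError(f"tissue {t!r} missing from amounts")
        if t not in volumes:
            raise KeyError(f"tissue {t!r} missing from volumes")
    return sum(amounts[t] for t in lump) / sum(volumes[t] for t in lump)


@dataclass
class PKProfile:
    """Simulation output: time grid, state trajectories and derived observables."""

    t_h: np.ndarray
    states: np.ndarray  # (n_times, N_STATES)
    params: ModelParams
    doses_nmol: tuple = ()
    meta: dict = field(default_factory=dict)

    OBSERVABLES = ("plasma", "tight_total", "leaky_total")

    def observable(self, name: str, units: str = "nM") -> np.ndarray:
        """Named observable time course (``plasma``, ``tight_total``, ``leaky_total``).

        Lumped-tissue totals follow the volume-weighted sub-space mean with
        total (free + complexed) antibody per sub-space.
        """
        y = self.states
        ph = self.params.physiology
        if name == "plasma":
            out = y[:, A_P] + y[:, ATS_P]
        elif name in ("tight_total", "leaky_total"):
            i = 0 if name == "tight_total" else 1
            b = tissue_base(i)
            C_e = y[:, b + oA_E] + y[:, b + oATS_E] + y[:, b + oAF_E] + y[:, b + oATF_E]
            C_v = y[:, b + oA_V] + y[:, b + oATS_V] + y[:, b + oATM_V] + y[:, b + oARM_V]
            # interstitial states live in the accessible volume K_p*V_is
            C_is = (y[:, b + oA_IS] + y[:, b + oATS_IS]) * self.params.K_p
            V = ((ph.V_e_tight_L, ph.V_v_tight_L, ph.V_is_tight_L),
                 (ph.V_e_leaky_L, ph.V_v_leaky_L, ph.V_is_leaky_L))[i]
            out = lumped_tissue_concentration(C_e, C_v, C_is, *V)
        elif name in STATE_NAMES:
            out = y[:, STATE_NAMES.index(name)]
        else:
            raise KeyError(f"unknown observable {name!r}")
        if units == "nM":
            return out
        if units in ("ug/mL", "ug_per_mL"):
            return out * self.params.antibody.MW_Da * 1e-6
        raise ValueError(f"unknown units {units!r}")

    def to_frame(self, units: str = "nM"):
        """Tidy frame ``time_h, observable, value, unit`` for the three observables."""
        import pandas as pd

        rows = []
        for name in self.OBSERVABLES:
            vals = self.observable(name, units=units)
            rows.append(pd.DataFrame({"time_h": self.t_h, "observable": name,
                                      "value": vals, "unit": units}))
        return pd.concat(rows, ignore_index=True)
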