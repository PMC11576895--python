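"""ODE core: initial conditions, conservation laws, linearity, observables."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mpbpk
from mpbpk import core
from mpbpk.core import (
    A_P,
    F_EP,
    build_model_params,
    initial_state,
    lumped_tissue_concentration,
    observed_lumping,
    ode_rhs,
    tissue_base,
    total_antibody_amount,
)
from mpbpk.compound import AntibodyDescriptor, TargetDescriptor, mass_conc_to_nM


@pytest.fixture(scope="module")
def cea_case(fixtures):
    return fixtures["mouse_anti_cea"].build(1.0)


class TestInitialState:
    def test_dose_in_plasma_and_receptors_at_baseline(self, cea_case):
        params, _ = cea_case
        y = initial_state(params, 1.0)
        assert y[A_P] == pytest.approx(1.0 / params.physiology.V_p_L)
        assert y[F_EP] == params.FcRn_total
        for i in range(2):
            b = tissue_base(i)
            assert y[b + core.oTM_V] == 80.0  # membrane antigen baseline
            assert y[b + core.oTS_V] == pytest.approx(0.0111)
            assert y[b + core.oATM_V] == 0.0

    def test_soluble_baseline_from_mass_units(self, cea_case):
        # 2 ng/mL of the ~180 kDa antigen expressed in nM
        params, _ = cea_case
        y = initial_state(params, 0.0)
        assert y[core.TS_P] == pytest.approx(mass_conc_to_nM(2.0, 180000), rel=1e-2)

    def test_negative_dose_rejected(self, cea_case):
        with pytest.raises(ValueError):
            initial_state(cea_case[0], -1.0)

    def test_drug_free_steady_state(self, cea_case):
        """With no dose, all antigen states stay at baseline over 1000 h."""
        params, _ = cea_case
        y0 = initial_state(params, 0.0)
        rhs = core.make_rhs(params)
        sol = solve_ivp(rhs, (0, 1000.0), y0, method="LSODA",
                        rtol=params.rtol, atol=params.atol)
        assert sol.success
        scale = np.maximum(np.abs(y0), 1e-6)
        assert np.max(np.abs(sol.y[:, -1] - y0) / scale) < 1e-6

    def test_membrane_degradation_rate_from_halflife(self, cea_case):
        # the 36 h membrane-antigen half-life corresponds to 0.019 1/h
        params, _ = cea_case
        assert params.target.k_p_Tm == pytest.approx(np.log(2) / 36.0, rel=1e-3)
        assert round(params.target.k_p_Tm, 3) == 0.019


class TestConservation:
    def test_antibody_mass_conserved_without_elimination(self, wt_case):
        params, sched = wt_case
        p0 = params.with_overrides(k_deg=0.0, CL_renal=0.0)
        prof = mpbpk.simulate(p0, sched, t_end=2000.0)
        a0 = total_antibody_amount(prof.states[0], p0)
        drift = max(abs(total_antibody_amount(y, p0) - a0) for y in prof.states[::10])
        assert drift / a0 < 1e-6

    def test_fcrn_conserved_in_every_endosome(self, wt_profile):
        y = wt_profile.states
        tot = wt_profile.params.FcRn_total
        for cols in ([F_EP, core.AF_EP, core.ATF_EP],
                     [tissue_base(0) + o for o in (core.oF_E, core.oAF_E, core.oATF_E)],
                     [tissue_base(1) + o for o in (core.oF_E, core.oAF_E, core.oATF_E)]):
            s = y[:, cols].sum(axis=1)
            assert np.max(np.abs(s - tot)) <= 1e-8 * tot

    def test_membrane_nsb_pool_conserved(self, fixtures):
        params, sched = fixtures["mouse_igg_charge_pos5"].build()
        prof = mpbpk.simulate(params, sched, t_end=200.0)
        # free Rm is algebraic (R_m_total - ARm), so the bound pool can never
        # exceed the fixed total
        for i in range(2):
            arm = prof.states[:, tissue_base(i) + core.oARM_V]
            assert np.all(arm >= -1e-9)
            assert np.all(arm <= params.R_m_total * (1 + 1e-9))

    def test_elimination_closes_the_mass_balance(self, wt_case):
        """d/dt(total antibody) equals minus the sum of elimination fluxes."""
        params, sched = wt_case
        prof = mpbpk.simulate(params, sched, t_end=504.0)
        p = params.prepare()
        y = prof.states[len(prof.t_h) // 2]
        dy = ode_rhs(0.0, y, params)
        d_amount = (dy[A_P] + dy[core.ATS_P]) * p.V_p
        d_amount += (dy[core.A_EP] + dy[core.ATS_EP] + dy[core.AF_EP] + dy[core.ATF_EP]) * p.V_ep
        d_amount += (dy[core.A_LY] + dy[core.ATS_LY]) * p.V_ly
        elim = p.k_deg * y[core.A_EP] * p.V_ep
        for i in range(2):
            b = tissue_base(i)
            for o in (core.oA_V, core.oATS_V, core.oATM_V, core.oARM_V):
                d_amount += dy[b + o] * p.V_v[i]
            for o in (core.oA_E, core.oATS_E, core.oAF_E, core.oATF_E):
                d_amount += dy[b + o] * p.V_e[i]
            for o in (core.oA_IS, core.oATS_IS):
                d_amount += dy[b + o] * p.V_is_acc[i]
            elim += p.k_deg * y[b + core.oA_E] * p.V_e[i]
            elim += p.kcat[i] * y[b + core.oATS_E] * p.V_e[i]
            elim += p.k_int * y[b + core.oATM_V] * p.V_v[i]
            elim += p.k_int_ARm[i] * y[b + core.oARM_V] * p.V_v[i]
            if i == 1:
                elim += p.CL_renal * (y[b + core.oA_V] + y[b + core.oATS_V])
        elim += p.kcat_p * y[core.ATS_EP] * p.V_ep
        assert d_amount == pytest.approx(-elim, rel=1e-9, abs=1e-15)


class TestLinearity:
    def test_dose_proportionality_without_tmdd_or_nsb(self, wt_case):
        params, _ = wt_case
        from mpbpk import DoseSchedule, dose_to_amount

        bw, mw = params.physiology.body_weight_kg, params.antibody.MW_Da
        t = np.linspace(0, 504, 40)
        lo = mpbpk.simulate(params, DoseSchedule.from_mg_per_kg(0.8, bw, mw), t_grid=t)
        hi = mpbpk.simulate(params, DoseSchedule.from_mg_per_kg(8.0, bw, mw), t_grid=t)
        ratio = hi.observable("plasma")[1:] / lo.observable("plasma")[1:]
        # the only saturable pool left is endosomal FcRn, whose occupancy
        # stays below 0.03% at these doses; the ratio is 10 to that accuracy
        assert np.allclose(ratio, 10.0, rtol=2e-4)
        # with no saturable pool at all the system is exactly linear
        ko = params.with_overrides(FcRn_total_nM=0.0)
        lo = mpbpk.simulate(ko, DoseSchedule.from_mg_per_kg(0.8, bw, mw), t_grid=t)
        hi = mpbpk.simulate(ko, DoseSchedule.from_mg_per_kg(8.0, bw, mw), t_grid=t)
        ratio = hi.observable("plasma")[1:] / lo.observable("plasma")[1:]
        assert np.allclose(ratio, 10.0, rtol=1e-6)

    def test_fcrn_knockout_matches_reduced_model_oracle(self, wt_case):
        """With FcRn_total = 0 the trajectories match an independently coded
        antibody-only model with the FcRn states removed."""
        params, sched = wt_case
        p0 = params.with_overrides(FcRn_total_nM=0.0)
        p = p0.prepare()

        def reduced_rhs(t, x):
            a_p, a_ep, a_ly, av1, ae1, ais1, av2, ae2, ais2 = x
            dx = np.zeros(9)
            dx[1] = p.CL_up_p * a_p / p.V_ep - p.k_deg * a_ep
            flow = -(p.Q[0] + p.Q[1]) * a_p + p.L_tot * a_ly
            dx[0] = (flow - p.CL_up_p * a_p) / p.V_p
            dly = -p.L_tot * a_ly
            for i, (av, ae, ais) in enumerate([(av1, ae1, ais1), (av2, ae2, ais2)]):
                (J1s, Pe, PS), = p.flux_classes[i]  # lumped single class
                em = np.exp(-Pe)
                J = J1s * (av - ais * em) / (1 - em)
                renal = p.CL_renal if i == 1 else 0.0
                k = 3 + 3 * i
                dx[k] = (p.Q[i] * a_p - (p.Q[i] - p.L[i]) * av - J
                         - p.CL_up[i] * av - renal * av) / p.V_v[i]
                dx[k + 1] = p.CL_up[i] * (av + ais) / p.V_e[i] - p.k_deg * ae
                drain = p.L[i] * (1 - p.sigma_L)
                dx[k + 2] = (J - drain * ais - p.CL_up[i] * ais) / p.V_is_acc[i]
                dx[0] += (p.Q[i] - p.L[i]) * av / p.V_p
                dly += drain * ais
            dx[2] = dly / p.V_ly
            return dx

        amount = sched.events[0][1]
        x0 = np.zeros(9)
        x0[0] = amount / p.V_p
        t_grid = np.linspace(0, 300, 30)
        sol = solve_ivp(reduced_rhs, (0, 300), x0, t_eval=t_grid, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        full = mpbpk.simulate(p0, sched, t_grid=t_grid)
        np.testing.assert_allclose(full.observable("plasma")[1:], sol.y[0, 1:], rtol=1e-5)

    def test_non_finite_state_rejected_with_index(self, wt_case):
        params, _ = wt_case
        y = initial_state(params, 1.0)
        y[7] = np.nan
        with pytest.raises(ValueError, match="index 7"):
            ode_rhs(0.0, y, params)


class TestObservables:
    def test_lumped_concentration_examples(self):
        assert lumped_tissue_concentration(3.0, 3.0, 3.0, 1.0, 2.0, 7.0) == pytest.approx(3.0)
        assert lumped_tissue_concentration(0.0, 10.0, 0.0, 1.0, 2.0, 7.0) == pytest.approx(2.0)

    def test_lumped_concentration_matches_dot_product_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            c = rng.uniform(0, 100, 3)
            v = rng.uniform(0.01, 5, 3)
            assert lumped_tissue_concentration(*c, *v) == pytest.approx(np.dot(c, v) / v.sum())

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            lumped_tissue_concentration(1, 1, 1, 0.0, 1.0, 1.0)

    def test_observed_lumping(self):
        amounts = {"brain": 2.0, "muscle": 2.0, "skin": 2.0, "adipose": 2.0}
        volumes = {"brain": 0.5, "muscle": 0.5, "skin": 0.5, "adipose": 0.5}
        assert observed_lumping(amounts, volumes, list(amounts)) == pytest.approx(4.0)
        assert observed_lumping(amounts, volumes, ["brain"]) == pytest.approx(4.0)
        rng = np.random.default_rng(7)
        a = {k: rng.uniform(0, 5) for k in amounts}
        v = {k: rng.uniform(0.1, 2) for k in amounts}
        keys = list(amounts)
        assert observed_lumping(a, v, keys) == pytest.approx(
            sum(a[k] for k in keys) / sum(v[k] for k in keys)
        )
        with pytest.raises(KeyError, match="liver"):
            observed_lumping(amounts, volumes, ["brain", "liver"])

    def test_tissue_total_is_volume_weighted_total_antibody(self, wt_profile):
        prof = wt_profile
        ph = prof.params.physiology
        y = prof.states[-1]
        b = tissue_base(0)
        C_e = y[b + core.oA_E] + y[b + core.oATS_E] + y[b + core.oAF_E] + y[b + core.oATF_E]
        C_v = y[b + core.oA_V] + y[b + core.oATS_V] + y[b + core.oATM_V] + y[b + core.oARM_V]
        C_is = (y[b + core.oA_IS] + y[b + core.oATS_IS]) * prof.params.K_p
        expected = (C_e * ph.V_e_tight_L + C_v * ph.V_v_tight_L + C_is * ph.V_is_tight_L) / (
            ph.V_e_tight_L + ph.V_v_tight_L + ph.V_is_tight_L
        )
        assert prof.observable("tight_total")[-1] == pytest.approx(expected)

    def test_mass_units_conversion(self, wt_profile):
        nm = wt_profile.observable("plasma")
        ug = wt_profile.observable("plasma", units="ug/mL")
        assert ug[0] == pytest.approx(nm[0] * 150000 * 1e-6)


class TestParamResolution:
    def test_charge_parameters_resolved_from_descriptor(self, mouse):
        ab = AntibodyDescriptor(name="pos", MW_Da=150000, net_charge=5.0)
        params = build_model_params(mouse, ab, overrides={"R_m_total": 71.86})
        assert params.K_p == pytest.approx(0.8)
        assert params.K_D_NSB == pytest.approx(1.21, rel=0.01)
        assert params.S_pino_2 == pytest.approx(2.99)
        assert params.S_pino_1 == 1.0

    def test_renal_clearance_wired_to_leaky_vascular_only(self, mouse):
        """Renal elimination acts on leaky vascular antibody and nowhere else."""
        ab = AntibodyDescriptor(name="fab", MW_Da=50000, fcrn_binding=False)
        params = build_model_params(mouse, ab)
        assert params.CL_renal > 1e-4
        y = initial_state(params, 1.0)
        b1, b2 = tissue_base(0), tissue_base(1)
        y[b1 + core.oA_V] = 50.0
        y[b2 + core.oA_V] = 50.0
        base = ode_rhs(0.0, y, params)
        bumped = ode_rhs(0.0, y, params.with_overrides(CL_renal=2 * params.CL_renal))
        delta = bumped - base
        expected = -params.CL_renal * 50.0 / params.physiology.V_v_leaky_L
        assert delta[b2 + core.oA_V] == pytest.approx(expected)
        mask = np.ones(core.N_STATES, bool)
        mask[[b2 + core.oA_V, b2 + core.oATS_V]] = False
        assert np.allclose(delta[mask], 0.0)

    def test_sigma_overrides_take_precedence_over_derived(self, mouse):
        ab = AntibodyDescriptor(name="igg", MW_Da=150000)
        derived = build_model_params(mouse, ab)
        fitted = build_model_params(mouse, ab, overrides={"sigma_1": 0.9, "sigma_2": 0.86})
        assert derived.sigma_1 == pytest.approx(derived.tp_tight.sigma_eff)
        assert fitted.sigma_1 == 0.9 and fitted.sigma_2 == 0.86

    def test_soluble_target_without_catabolism_rejected(self, mouse):
        ab = AntibodyDescriptor(name="igg", MW_Da=150000)
        tgt = TargetDescriptor(T_s0_nM=1.0, soluble_halflife_h=2.0, CL_cat_L_per_h=0.0)
        with pytest.raises(ValueError, match="CL_cat"):
            build_model_params(mouse, ab, tgt)
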