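# mpbpk — minimal PBPK modelling of antibody pharmacokinetics

`mpbpk` is a Python package for pharmacokinetic modellers and
antibody-engineering teams who need to ask: *how do molecular weight and
size, net surface charge, FcRn affinity and antigen affinity jointly shape
the plasma and tissue PK of a large-molecule drug?*

It implements a minimal physiologically based pharmacokinetic (mPBPK)
model: plasma (with a nested endothelial endosome), lymph, and two lumped
tissues — *tight* (brain + muscle + skin + adipose) and *leaky* (the rest)
— each split into vascular, endosomal and interstitial sub-spaces. On top
of the 39-state ODE core it provides:

* **two-pore transcapillary transport** — for a solute of Stokes radius
  `a_e` (`a_e = 0.0483·MW^0.386` nm), small/large pore hindrance factors,
  reflection coefficients `σ = 1 − Φ(2−Φ)(1−λ²/3)` with `Φ = (1−λ)²`,
  Patlak convection–diffusion fluxes, and size-based renal clearance
  `CL_renal = GFR·θ(a_e)` from a fitted glomerular sieving curve;
* **FcRn salvage** — pH-6 endosomal binding, recycling with clearance
  `V_e/τ` (τ = 8 min), lysosomal degradation of unbound antibody;
* **charge effects** — fitted empirical relations `K_p(z)` (accessible
  interstitial volume), `K_D,NSB(z)` (non-specific membrane binding) and
  `S_pino(z)` (pinocytosis scaling), anchored at measured −8 / 0 / +5
  charge variants;
* **target-mediated drug disposition** — soluble and membrane antigens
  with synthesis/degradation turnover and complex internalisation;
* **estimation** — local sensitivity (ΔAUC% for +20% bumps) and
  multi-start nonlinear least squares (Latin-hypercube starts,
  mean-normalised SSE), plus a synthetic-data generator so every fitting
  pathway is testable without external datasets.

## Worked example

Simulate a wild-type mouse receiving 8 mg/kg of a non-specific
FcRn-binding IgG and report plasma and lumped-tissue concentrations:

```python
import numpy as np
import mpbpk

scenario = mpbpk.scenario_fixtures()["mouse_igg_wt"]
params, schedule = scenario.build()          # 8 mg/kg IV bolus, 28 g mouse
profile = mpbpk.simulate(params, schedule, t_end=504.0)

for t in (1, 24, 168, 504):
    p, ti, le = (np.interp(t, profile.t_h, profile.observable(o))
                 for o in ("plasma", "tight_total", "leaky_total"))
    print(f"t={t:4g} h  plasma={p:8.1f} nM  tight={ti:6.2f} nM  leaky={le:7.2f} nM")
print(mpbpk.terminal_clearance(profile))
```

```
t=   1 h  plasma=   805.1 nM  tight= 97.67 nM  leaky= 190.49 nM
t=  24 h  plasma=   620.4 nM  tight=128.12 nM  leaky= 204.43 nM
t= 168 h  plasma=   555.9 nM  tight=126.25 nM  leaky= 182.58 nM
t= 504 h  plasma=   466.8 nM  tight=105.99 nM  leaky= 153.29 nM
{'kel_per_h': 0.00052..., 'CL_L_per_h': 4.9e-07, 'CL_L_per_h_per_kg': 1.75e-05}
```

The 8 mg/kg bolus dilutes into the 0.944 mL plasma volume to ~1580 nM,
distributes within hours into the tissue lumps (tight tissue peaks near
128 nM — vascular reflection σ₁ = 0.9 keeps most antibody out of the
interstitium), then declines slowly: FcRn rescues ~90% of pinocytosed
antibody, so the terminal elimination rate is only ~5×10⁻⁴ 1/h. Setting
`FcRn_total_nM=0` (knockout) shortens the terminal half-life about
sevenfold.

The same library surface drives fitting:

```python
ds = mpbpk.generate_pk_dataset(params, schedule, mpbpk.NoiseModel(kind="none"))
spec = mpbpk.FitSpec(bounds={"k_up": (3e-4, 3.0)}, n_starts=10, seed=1)
fit = mpbpk.fit_to_dataset(params, schedule, ds.fit_frame, spec)
print(fit.best_params)   # {'k_up': 0.0276...} — recovers the generating value
```

A thin CLI mirrors the library: `mpbpk two-pore --mw 150000`,
`mpbpk charge --z -4`, `mpbpk simulate --scenario mouse_anti_cea --out p.csv`,
`mpbpk sensitivity --scenario mouse_igg_wt`, `mpbpk fit ...`.

Packaged scenarios cover wild-type and FcRn-knockout mouse IgG (8 mg/kg),
50/100/150 kDa size variants (5 mg/kg), −8/0/+5 charge variants
(10 mg/kg), an anti-CEA antibody with membrane-target TMDD (1/10/25
mg/kg), and a human anti-TNF-α antibody (1/3/5 mg/kg). Model structure and
defaults are documented in [`docs/methods.md`](docs/methods.md).

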