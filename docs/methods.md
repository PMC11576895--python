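# Methods

## Model overview

`mpbpk` implements a minimal physiologically based pharmacokinetic (mPBPK)
model for monoclonal antibodies and antibody fragments that links four
physicochemical axes — molecular weight/size, net surface charge, FcRn
binding affinity, and antigen binding affinity — to plasma and tissue
pharmacokinetics.

The body is reduced to four compartments: plasma (with a nested endosomal
sub-compartment representing the systemic vascular endothelium), lymph, and
two lumped tissues. The *tight* lump aggregates brain, muscle, skin and
adipose — tissues whose capillary pore-size upper limit is small — and the
*leaky* lump aggregates every other tissue. Each lumped tissue splits into
vascular, endothelial-endosomal and interstitial sub-spaces with
physiological volumes summed from a per-tissue table. The state vector
holds 39 concentrations: antibody (A), soluble antigen (Ts), membrane
antigen (Tm), FcRn (F) and their complexes, distributed over these spaces.

Processes, in the order antibody encounters them after an IV bolus:

1. **Convective distribution.** Plasma flow `Q_i` carries antibody into each
   tissue vascular space; `Q_i − L_i` returns, and lymph flow `L_i` closes
   the fluid balance through the lymph compartment (solute drainage carries
   the factor `1 − σ_L`).
2. **Two-pore transcapillary transport.** Small (4.44 nm) and large
   (22.85 nm) cylindrical pores carry solute by coupled convection and
   hindered diffusion (Patlak flux per pore class). For a solute of Stokes
   radius `a_e`, `λ = a_e/r` gives the steric partition `(1−λ)²`, the
   Renkin diffusive hindrance polynomial, and a pore reflection coefficient
   `σ = 1 − Φ(2−Φ)(1−λ²/3)`. The effective vascular reflection coefficient
   is the conductance-weighted mean `σ_eff = α_s σ_s + α_l σ_l`.
3. **Pinocytosis and FcRn salvage.** Fluid-phase uptake moves antibody from
   the vascular and interstitial spaces into endothelial endosomes with
   clearance `S_pino,i · k_up · V_e,i` (and `k_up,p · V_ep` for the plasma
   nested endosome). At endosomal pH 6, antibody binds FcRn
   (`k1on/k1off`); bound antibody recycles with clearance
   `CL_rec = V_e/τ` (transit time τ = 8 min), split `f_rec_v : 1−f_rec_v`
   between the vascular and interstitial sides (the plasma nested endosome
   recycles wholly to plasma). Unbound endosomal antibody degrades at
   `k_deg`; unbound antigen and antibody–antigen complex are catabolised
   with clearance `CL_cat`.
4. **Target binding (TMDD).** Soluble antigen is synthesised in plasma and
   tissue vascular spaces (`k_syn = baseline × elimination rate`), membrane
   antigen in tissue vascular space (`k_syn,m = T_m0 · k_p,Tm`). Binding
   uses pH-7.4 kinetics (`kon/koff`) outside endosomes and pH-6 kinetics
   (`keon/keoff`) inside; endosomal pH is not a state. Membrane complexes
   internalise at `k_int` and leave the tracked system.
5. **Charge effects.** Net surface charge `z` enters through three fitted
   empirical relations: the accessible interstitial volume fraction
   `K_p(z)` (quadratic pinned at `K_p(0)=1`, capped at 1), the non-specific
   membrane binding constant `K_D,NSB(z)` (log-space logistic, strictly
   decreasing), and the pinocytosis scaling `S_pino(z)` (1 in tight tissue
   and for z ≤ 0; linear through (0, 1) and (+5, 2.99) in leaky tissue,
   clamped at z = +10). Non-specific binding to membrane constituents uses
   `k_on,NSB = k1on` by construction; NSB-internalised antibody is
   eliminated (see design choices).
6. **Renal elimination.** A glomerular sieving coefficient `θ(a_e)`
   (logistic fit to a packaged sieving table) multiplies GFR to give
   `CL_renal`, applied to antibody in the leaky vascular space only.
   `θ ≤ 10⁻³` above 4 nm, so renal loss matters only for fragments.

Lumped observables follow the volume-weighted sub-space mean
`C_total = (C_e V_e + C_v V_v + C_is V_is)/(V_e + V_v + V_is)` with total
(free + complexed) antibody per sub-space; interstitial amounts account for
the accessible volume `K_p V_is`.

## Key parameters, units and defaults

| Parameter | Meaning | Default | Unit |
|---|---|---|---|
| `k_up`, `k_up_p` | endosomal uptake rates (tissue, plasma-nested) | 0.0366 | 1/h |
| `k_deg` | lysosomal degradation of free endosomal antibody | 60 | 1/h |
| `τ` | endosomal transit time (sets `CL_rec = V_e/τ`) | 8 | min |
| `FcRn_total` | endosomal FcRn concentration | 49 800 | nM |
| `σ_L` | lymphatic reflection coefficient | 0.2 | – |
| `f_rec_v` | recycled fraction routed to vascular side | 0.5 | – |
| `r_small`, `r_large` | pore radii | 4.44, 22.85 | nm |
| `α_large` | large-pore fraction of hydraulic conductance | 0.042 | – |
| `a_e` | Stokes radius, `0.0483·MW^0.386` unless supplied | derived | nm |
| mouse GFR | glomerular filtration rate (28 g) | 0.01668 | L/h |

Fitted study values (wild-type mouse): `k_up = 0.0276`, `k_up,p = 0.05`,
`σ₁ = 0.9`, `σ₂ = 0.86`; knockout `k_up = 0.15`; neutral-variant
`R_m,total = 71.86 nM`, `K_D,NSB = 8.35 nM`; +5 variant `S_pino,2 = 2.99`,
`K_D,NSB = 1.21 nM`, `K_p = 0.8`; −8 variant `K_D,NSB = 16.22 nM`,
`K_p = 0.62`; anti-CEA `k_int = 0.015 1/h` with a 36 h membrane-target
half-life (`k_p,Tm = ln2/36 ≈ 0.019 1/h`). These live in the packaged
scenario files, not in code.

`k_deg = 60 1/h` is a lumped lysosomal-sorting rate chosen so that, with
the default FcRn pool and affinity, roughly 90% of endosomal uptake is
salvaged — consistent with the reported efficiency of FcRn rescue. With
this default the mouse configuration gives a terminal half-life of ~180 h
without FcRn versus ~1300 h with it, i.e. knockout shortens the half-life
about sevenfold.

## Physiology tables

Mouse (28 g) and human (70 kg) per-tissue tables ship as editable CSV
config using standard fractional rules (plasma-volume fraction 2–9% of
tissue volume, interstitial 13–33%, endosomal 0.5%, lymph flow 0.2% of
plasma flow); species-level values (plasma volume, GFR, FcRn, transit
time) sit in YAML. They are representative literature-style values
assembled for this package, not a transcription of any single published
table; all downstream results that matter here (parameter recovery,
conservation, orderings) are invariant to moderate changes in them. The
nested plasma endosome volume `V_ep` (0.1 mL mouse / 15 mL human)
represents the endosomal pool of the extra-organ vascular endothelium and
is configurable.

## Synthetic data

`synthetic.generate_pk_dataset` samples the three observables at assay-like
times, optionally applies multiplicative log-normal noise with median
preserved (`sd_log = √ln(1+cv²)`, default cv = 0.15, a typical preclinical
PK assay variability) and censors below an optional LLOQ (flagged, never
dropped). It emulates noiseless or noisy measurements of the model's own
output; it does **not** emulate inter-animal variability, sparse/irregular
designs, assay bias, or model misspecification. Passing recovery tests
therefore demonstrates estimator correctness and identifiability under the
stated design — not that the model is correct for any particular real
dataset.

The packaged sieving table (`sieving_synthetic.csv`) is a synthetic
stand-in with a literature-like shape (free filtration of small tracers, a
steep cutoff near 3 nm, negligible sieving above 4 nm); the logistic
`θ(a_e)` is refit from it at import time, so replacing the CSV with real
sieving measurements changes the renal model without touching code.

## Numerical choices

* Stiff integration with LSODA, `rtol = 1e-8`, `atol = 1e-10 nM` (exposed
  on `ModelParams`); IV boluses are instantaneous plasma increments between
  integration segments; output grids are log-dense with ≥200 points per
  dosing phase.
* The Patlak flux uses the analytic diffusion limit for `Pe < 1e-10`,
  never a division by `1 − e^{−Pe}` near zero.
* Free antigen inside tissue endosomes enters through pinocytosis, so the
  drug-free steady state of the antigen sub-system is computed and used as
  the initial condition, and synthesis rates include the (small)
  compensation for pinocytic loss so the stated baselines are an exact
  steady state.
* Fitting minimises SSE normalised by the observed mean (residuals
  weighted `1/√mean(obs)` per observable block) with bounded
  trust-region least squares; rates are fitted on a log10 scale, bounded
  fractions (σ, K_p, f_rec_v) on a linear scale. The finite-difference
  step (`diff_step = 1e-3` in internal coordinates) is set well above the
  integrator's relative noise so gradients stay smooth along shallow
  valleys; this matters for the k_up/k_up,p trade-off, which is broken
  only by second-order features of the tissue curves. Latin-hypercube
  starts come from a seeded `scipy.stats.qmc` sampler; everything is
  deterministic given the seed.
* Local sensitivity uses one-at-a-time +20% bumps; bounded coefficients
  are clipped to their admissible interval (σ at 0.999, K_p at 1) after
  perturbation, and a failed perturbed simulation is recorded as missing.

## Design choices where the design was open

* **σ precedence.** User-supplied or fitted σ₁/σ₂ replace the two-pore
  derived `σ_eff`; in that case the transcapillary flux collapses to the
  equivalent single-membrane Patlak form with the tissue's total PS.
  Without an override, the per-pore-class two-pore fluxes are used (size
  variants are pure predictions).
* **Uptake sides and recycling split.** Tissue endosomes draw at full
  clearance from both their vascular and interstitial faces, and recycling
  returns antibody to both, split by `f_rec_v = 0.5` (configurable): the
  endothelium contacts both spaces and no asymmetry is specified.
* **NSB internalisation.** Membrane-bound (ARm) antibody internalises at
  `S_pino·k_up` with the membrane constituent returned to the free pool;
  the internalised antibody leaves the tracked system, like internalised
  target complexes. Routing it into the endosome instead would let FcRn
  recycle ~90% of it and nearly cancel charge-dependent clearance.
* **K_D,NSB(z) functional form.** An interpolating quadratic through the
  three charge anchors goes negative above z ≈ +9, and a log-space
  quadratic is non-monotone below z ≈ −6; both violate the physical
  requirements (positive, strictly decreasing). The log-space logistic
  with fixed width w = 2 passes the three anchors exactly and satisfies
  both requirements over the whole validity range z ∈ [−10, +10]. Charges
  outside that range clamp with a logged warning.
* **Soluble antigen flow.** Antigen exchanges between plasma and tissue
  vascular space with symmetric flow `Q_i` (no antigen lymph pathway);
  asymmetric flow would demand negative synthesis rates to hold the
  baseline. Antibody flow remains asymmetric and exactly mass-conserving.
* **Unknown tissues.** Per-tissue tables are validated against a tissue
  vocabulary so a typo cannot silently land a tight tissue in the leaky
  lump.

## Problem sizes

Recovery experiments sample 12 time points per observable (36 residuals)
over 21 days at the study doses, with 10 Latin-hypercube starts per fit —
enough to make every fitted parameter identifiable from noiseless data
while keeping a full recovery campaign at a few hundred ODE solves per
start. The noisy-replicate property test uses 5 replicates of the
one-parameter knockout fit at cv = 0.15.

## Known limitations

* IV bolus only; no subcutaneous absorption, no pharmacodynamics, no
  downstream cellular processing of internalised complexes.
* Tissue resolution stops at the two lumps; individual-tissue predictions
  require the per-tissue model the lumping was derived from.
* The charge relations are anchored at three variants of one antibody
  scaffold; outside z ∈ [−10, +10] the model clamps rather than
  extrapolates, and charge-dependent FcRn affinity changes are not
  modelled.
* Glomerular sieving depends on size only (no charge selectivity).
* Weak FcRn occupancy (<0.03% at study doses) makes dose-linearity exact
  only in the knockout limit; at therapeutic doses the deviation is below
  2×10⁻⁴ relative.
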