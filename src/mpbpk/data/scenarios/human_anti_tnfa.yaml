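# Human (70 kg) anti-TNF-alpha IgG at 1/3/5 mg/kg IV, simulated over 700 h.
# Soluble-target baseline 0.276 pM; soluble-target elimination given as a
# clearance (8.316 L/h). Transport coefficients are two-pore derived.
name: human_anti_tnfa
species: human
antibody:
  name: anti_TNFa_IgG
  MW_Da: 148000.0
  net_charge: 0.0
  fcrn_binding: true
  k1on: 0.1
  k1off: 70.0
  kon: 0.3
  koff: 0.03
  keon: 0.3
  keoff: 0.03
target:
  name: TNFa_soluble
  T_s0_nM: 2.76e-4
  T_m0_nM: 0.0
  CL_pT_L_per_h: 8.316
  CL_cat_L_per_h: 0.01
doses_mg_per_kg: [1.0, 3.0, 5.0]
t_end_h: 700.0
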