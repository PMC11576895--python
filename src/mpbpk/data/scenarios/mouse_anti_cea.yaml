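# Target-mediated disposition: anti-CEA IgG in mice at 1/10/25 mg/kg IV.
# Membrane antigen baseline 80 nM, half-life 36 h (k_p_Tm = ln2/36);
# complex internalization rate fitted at 0.015 1/h. Soluble antigen at
# 2 ng/mL (CEA MW ~180 kDa -> 0.0111 nM) with a 2 h half-life.
name: mouse_anti_cea
species: mouse
antibody:
  name: anti_CEA_IgG
  MW_Da: 150000.0
  net_charge: 0.0
  fcrn_binding: true
  k1on: 0.1
  k1off: 70.0
  kon: 0.03
  koff: 0.3
  keon: 0.03
  keoff: 0.3
target:
  name: CEA
  T_s0_nM: 0.0111
  T_m0_nM: 80.0
  soluble_halflife_h: 2.0
  k_p_Tm: 0.019254
  k_int: 0.015
  CL_cat_L_per_h: 0.001
doses_mg_per_kg: [1.0, 10.0, 25.0]
t_end_h: 504.0
overrides:
  k_up: 0.0276
  k_up_p: 0.05
  sigma_1: 0.9
  sigma_2: 0.86
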