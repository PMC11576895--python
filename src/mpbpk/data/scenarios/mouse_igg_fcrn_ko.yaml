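# FcRn-knockout mouse (endosomal FcRn = 0): pinocytosis becomes the
# rate-limiting elimination step and k_up is recalibrated upward.
name: mouse_igg_fcrn_ko
species: mouse
antibody:
  name: IgG1_wt
  MW_Da: 150000.0
  net_charge: 0.0
  fcrn_binding: true
  k1on: 0.1
  k1off: 70.0
doses_mg_per_kg: [8.0]
t_end_h: 504.0
overrides:
  FcRn_total_nM: 0.0
  k_up: 0.15
  k_up_p: 0.05
  sigma_1: 0.9
  sigma_2: 0.86
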