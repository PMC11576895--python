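# Size-variant evaluation: one-armed 100 kDa IgG, 5 mg/kg IV (derived sigmas).
name: mouse_igg_100kda
species: mouse
antibody:
  name: IgG_100kDa
  MW_Da: 100000.0
  net_charge: 0.0
  fcrn_binding: true
  k1on: 0.1
  k1off: 70.0
doses_mg_per_kg: [5.0]
t_end_h: 504.0
overrides:
  k_up: 0.0276
  k_up_p: 0.05
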