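# Charge-variant calibration case: neutral (z = 0) 150 kDa IgG, 10 mg/kg IV,
# non-specific membrane binding active (R_m,total estimated for this case).
name: mouse_igg_charge_neutral
species: mouse
antibody:
  name: IgG_z0
  MW_Da: 150000.0
  net_charge: 0.0
  fcrn_binding: true
  k1on: 0.1
  k1off: 70.0
doses_mg_per_kg: [10.0]
t_end_h: 504.0
overrides:
  k_up: 0.0276
  k_up_p: 0.05
  sigma_1: 0.9
  sigma_2: 0.86
  R_m_total: 71.86
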