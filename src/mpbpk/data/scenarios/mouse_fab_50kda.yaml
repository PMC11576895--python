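# Size-variant evaluation: 50 kDa Fc-less fragment, 5 mg/kg IV.
# No FcRn binding and a Stokes radius near 3.1 nm, so glomerular sieving
# gives a substantial size-based renal clearance.
name: mouse_fab_50kda
species: mouse
antibody:
  name: Fab_50kDa
  MW_Da: 50000.0
  net_charge: 0.0
  fcrn_binding: false
  k1on: 0.0
  k1off: 70.0
doses_mg_per_kg: [5.0]
t_end_h: 504.0
overrides:
  k_up: 0.0276
  k_up_p: 0.05
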