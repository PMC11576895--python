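# Species-level physiology, human (70 kg). Units in key names.
# GFR is a normal-kidney-function adult value; FcRn concentration kept at
# the endosomal value also used for mouse. Editable configuration.
species_name: human
body_weight_kg: 70.0
V_p_L: 3.126
V_lymph_L: 0.274
V_ep_L: 0.015
FcRn_total_nM: 49800.0
GFR_L_per_h: 6.3
endosomal_transit_time_h: 0.13333333333333333
sigma_L: 0.2
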