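# Species-level physiology, mouse (28 g). Units in key names.
# GFR and endosomal quantities are literature-derived defaults; the nested
# plasma endosome volume V_ep_L represents the endosomal pool of the
# systemic (extra-organ) vascular endothelium. Editable configuration.
species_name: mouse
body_weight_kg: 0.028
V_p_L: 9.44e-4
V_lymph_L: 1.13e-4
V_ep_L: 1.0e-4
FcRn_total_nM: 49800.0
GFR_L_per_h: 0.01668
endosomal_transit_time_h: 0.13333333333333333
sigma_L: 0.2
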