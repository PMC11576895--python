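# Per-tissue physiology, human (70 kg). Volumes in L, flows in L/h.
# Representative literature-style values assembled for this package using
# the same fractional rules as the mouse table. Editable configuration.
tissue,V_v_L,V_e_L,V_is_L,Q_L_per_h,L_L_per_h
brain,0.032,0.00725,0.261,21.45,0.0429
muscle,0.650,0.1476,3.84,27.0,0.054
skin,0.128,0.01704,1.125,11.6,0.0232
adipose,0.148,0.0673,2.289,9.8,0.0196
heart,0.013,0.00171,0.0487,9.0,0.018
lung,0.026,0.00263,0.0990,9.1,0.0182
kidney,0.018,0.00166,0.0498,37.1,0.0742
liver,0.157,0.00922,0.3687,48.3,0.0966
small_intestine,0.013,0.00419,0.1465,19.0,0.038
large_intestine,0.011,0.00265,0.0928,13.2,0.0264
spleen,0.022,0.00086,0.0363,5.2,0.0104
pancreas,0.006,0.00052,0.0168,3.1,0.0062
bone,0.224,0.0508,1.891,5.1,0.0102
thymus,0.001,0.0001,0.0035,0.7,0.0014
other,0.045,0.0070,0.242,7.9,0.0158
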