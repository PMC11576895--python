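# Per-tissue physiology, mouse (28 g). Volumes in L, flows in L/h.
# Representative literature-style values assembled for this package
# (plasma-volume fractions 2-9% of tissue volume, interstitial fractions
# 13-33%, endosomal volume 0.5% of tissue volume, lymph flow 0.2% of
# plasma flow). Editable configuration, not code.
tissue,V_v_L,V_e_L,V_is_L,Q_L_per_h,L_L_per_h
brain,1.07e-5,2.4e-6,8.73e-5,1.18e-2,2.36e-5
muscle,2.49e-4,5.65e-5,1.47e-3,8.61e-2,1.722e-4
skin,1.88e-4,2.51e-5,1.66e-3,2.78e-2,5.56e-5
adipose,2.18e-5,9.9e-6,3.37e-4,1.34e-2,2.68e-5
heart,5.8e-6,8.0e-7,2.17e-5,3.65e-2,7.3e-5
lung,1.05e-5,1.0e-6,3.84e-5,2.40e-2,4.8e-5
kidney,2.89e-5,2.6e-6,7.88e-5,6.85e-2,1.37e-4
liver,1.64e-4,9.7e-6,3.85e-4,9.41e-2,1.88e-4
small_intestine,1.16e-5,3.6e-6,1.27e-4,5.81e-2,1.16e-4
large_intestine,5.0e-6,1.6e-6,5.5e-5,1.73e-2,3.46e-5
spleen,1.54e-5,6.0e-7,2.54e-5,8.18e-3,1.64e-5
pancreas,5.4e-6,5.0e-7,1.69e-5,6.24e-3,1.25e-5
bone,6.21e-5,1.41e-5,5.25e-4,1.52e-2,3.04e-5
thymus,5.0e-7,5.0e-8,1.6e-6,1.19e-3,2.4e-6
other,1.48e-5,2.3e-6,7.97e-5,1.09e-2,2.18e-5
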