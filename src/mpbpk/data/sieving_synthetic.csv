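# Synthetic glomerular sieving table: theta vs Stokes radius (nm).
# SYNTHETIC stand-in constructed for this package with a literature-like
# shape (free filtration of small tracers, steep cutoff near 3 nm,
# negligible sieving above 4 nm); not digitized from any publication.
# Generated from theta = 1/(1 + exp((a_e - 2.6)/0.2)).
a_e_nm,theta
0.5,0.999972
1.0,0.999665
1.5,0.995930
2.0,0.952574
2.2,0.880797
2.4,0.731059
2.6,0.500000
2.8,0.268941
3.0,0.119203
3.2,0.047426
3.4,0.017986
3.6,0.006693
3.8,0.002473
4.0,0.000911
4.5,0.000075
5.0,0.000006
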