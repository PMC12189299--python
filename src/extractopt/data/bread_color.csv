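bread,crust_L,crust_a,crust_b,crumb_L,crumb_a,crumb_b
P1,57.27 ± 0.85 a,7.33 ± 1.89 a,28.25 ± 1.55 b,58.33 ± 2.16 b,-6.08 ± 4.75 b,11.34 ± 0.30 c
P2,59.45 ± 1.20 a,5.49 ± 5.03 a,32.34 ± 1.70 a,61.36 ± 2.21 ab,2.15 ± 4.35 a,14.54 ± 0.89 b
P3,56.80 ± 2.41 a,8.72 ± 3.04 a,29.38 ± 1.19 b,62.46 ± 0.89 a,0.48 ± 0.22 a,17.46 ± 1.72 a
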