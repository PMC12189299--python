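bread,TPC,AA
P1,23.6 ± 0.9 c,3.90 ± 0.09 c
P2,27.2 ± 0.6 b,4.40 ± 0.12 b
P3,30.0 ± 0.8 a,7.00 ± 0.10 a
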