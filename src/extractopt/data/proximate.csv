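sample,moisture,protein,ash,tdf
C1,63.1 ± 0.5 b,8.1 ± 0.2 b,8.48 ± 0.03 b,60.4 ± 1.4 a
C2,69.6 ± 0.8 a,9.9 ± 0.2 a,9.03 ± 0.01 a,61.7 ± 0.3 a
C3,11.4 ± 0.3 c,10.5 ± 0.1 d,2.64 ± 0.01 d,32.1 ± 0.7 b
C4,11.7 ± 0.3 c,13.5 ± 0.1 c,4.00 ± 0.02 c,29.8 ± 0.4 c
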