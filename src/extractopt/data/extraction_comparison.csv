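sample,method,TPC,TFC,ChA,ChB,YPG,AA
C1,TM,185 ± 1 b,12 ± 1 b,2882 ± 210 b,2493 ± 120 b,2.00 ± 0.02 b,20.5 ± 0.8 b
C1,UAE,382 ± 3 a,20 ± 2 a,3514 ± 62 a,2899 ± 42 a,6.8 ± 0.3 a,26.0 ± 0.4 a
C2,TM,163 ± 8 b,11 ± 1 b,2012 ± 154 b,1600 ± 85 b,1.60 ± 0.04 b,22.0 ± 1.0 b
C2,UAE,270 ± 2 a,18 ± 2 a,3510 ± 150 a,2642 ± 165 a,5.8 ± 0.4 a,26.6 ± 0.3 a
C3,TM,203 ± 2 b,1.0 ± 0.1 b,222 ± 12 b,339 ± 22 b,1.78 ± 0.04 b,16.5 ± 0.8 b
C3,UAE,295 ± 3 a,1.6 ± 0.2 a,459 ± 25 a,606 ± 46 a,1.92 ± 0.03 a,26.1 ± 0.2 a
C4,TM,162 ± 6 b,0.9 ± 0.1 b,323 ± 15 b,425 ± 31 b,2.00 ± 0.05 b,16.4 ± 0.3 b
C4,UAE,241 ± 2 a,1.5 ± 0.2 a,545 ± 19 a,778 ± 55 a,2.28 ± 0.09 a,27.1 ± 0.3 a
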