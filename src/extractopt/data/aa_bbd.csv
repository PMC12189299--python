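run,C1_exp,C1_pred,C2_exp,C2_pred,C3_exp,C3_pred,C4_exp,C4_pred
1,20.2 ± 0.1,20.4,26.2 ± 0.4,26.4,20.9 ± 1.3,21.0,27.9 ± 0.1,28.0
2,20.7 ± 0.4,20.6,20.1 ± 0.1,20.1,22.3 ± 1.0,22.5,28.8 ± 0.7,28.7
3,23.9 ± 0.1,24.1,22.0 ± 0.8,22.1,18.6 ± 0.5,18.5,26.6 ± 0.5,26.7
4,19.1 ± 0.1,19.0,22.3 ± 0.3,22.2,20.7 ± 0.8,20.6,28.5 ± 0.9,28.4
5,25.6 ± 0.3,25.3,26.5 ± 0.4,26.2,19.2 ± 0.9,19.2,29.6 ± 0.4,29.7
6,24.5 ± 0.3,24.5,19.7 ± 0.7,19.7,21.9 ± 1.4,21.9,25.6 ± 0.2,25.9
7,25.2 ± 0.9,25.2,23.4 ± 0.3,23.4,19.7 ± 1.7,19.8,24.1 ± 0.9,23.9
8,20.8 ± 0.7,21.1,23.5 ± 0.1,23.7,20.8 ± 0.3,20.8,30.2 ± 0.7,30.1
9,22.1 ± 0.7,22.3,23.2 ± 0.2,23.3,26.7 ± 0.2,26.6,25.9 ± 0.9,25.7
10,22.4 ± 0.3,22.6,24.5 ± 0.4,24.7,24.3 ± 1.0,24.4,28.0 ± 0.4,27.8
11,20.0 ± 0.4,19.9,26.6 ± 0.3,26.4,26.5 ± 0.5,26.4,27.7 ± 0.2,27.9
12,21.8 ± 0.1,21.6,22.8 ± 0.1,22.7,24.0 ± 0.8,24.1,23.8 ± 0.4,24.1
13,22.6 ± 0.3,22.6,22.4 ± 0.6,22.4,23.4 ± 0.2,23.4,30.5 ± 0.2,30.5
14,22.6 ± 0.3,22.6,22.4 ± 0.6,22.4,23.4 ± 0.2,23.4,30.5 ± 0.2,30.5
15,22.6 ± 0.3,22.6,22.4 ± 0.6,22.4,23.4 ± 0.2,23.4,30.5 ± 0.2,30.5
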