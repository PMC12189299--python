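term,C1_ss,C1_p,C2_ss,C2_p,C3_ss,C3_p,C4_ss,C4_p
X1,370.01,<0.0001,0.20,0.8614,63.37,0.0015,57.20,0.0138
X2,369.48,0.1711,1529.25,<0.0001,11.98,0.1261,2.88,0.5518
X3,16562.61,<0.0001,59.53,0.0064,242.57,<0.0001,34.26,0.0497
X1^2,25.31,0.8805,770.88,<0.0001,2659.80,<0.0001,2692.59,<0.0001
X2^2,0.29,<0.0001,0.01,0.9776,125.43,<0.0001,6711.89,<0.0001
X3^2,136.81,0.0035,381.20,<0.0001,53.27,0.0031,2828.28,<0.0001
X1X2,144.05,0.0028,88.13,0.0014,16.05,0.0794,1299.16,<0.0001
X1X3,213.18,0.0005,976.22,<0.0001,0.58,0.7290,97.75,0.0021
X2X3,1392.16,<0.0001,10.02,0.2262,0.40,0.7728,207.11,<0.0001
Residual,264.66,,128.50,,93.99,,136.98,
Lack of fit,69.57,0.1308,39.35,0.0941,11.79,0.5044,55.02,0.0999
Pure error,195.09,,89.15,,82.21,,81.96,
Total,19475.60,,3943.94,,3281.72,,12582.01,
R2,0.986,,0.968,,0.971,,0.9875,
R2_adj,0.981,,0.954,,0.958,,0.9819,
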