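term,C1_ss,C1_p,C2_ss,C2_p,C3_ss,C3_p,C4_ss,C4_p
X1,24.54,<0.0001,36.27,<0.0001,13.20,0.0001,5.98,<0.0001
X2,4.29,0.0001,5.21,<0.0001,19.12,<0.0001,2.90,0.0030
X3,11.71,<0.0001,1.38,0.0133,0.26,0.5124,2.56,0.0049
X1^2,1.32,0.0160,1.18,0.0201,110.66,<0.0001,4.67,0.0006
X2^2,29.54,<0.0001,2.83,0.0009,8.45,0.0010,23.91,<0.0001
X3^2,7.59,<0.0001,11.00,<0.0001,5.42,0.0060,41.28,<0.0001
X1X2,14.06,<0.0001,19.97,<0.0001,0.28,0.4967,0.58,0.1462
X1X3,5.58,<0.0001,23.81,<0.0001,1.39,0.1363,51.29,<0.0001
X2X3,1.02,0.0315,13.12,<0.0001,0.01,0.9269,17.47,<0.0001
Residual,3.80,,3.74,,11.50,,5.10,
Lack of fit,0.90,0.1925,0.54,0.4324,0.33,0.9153,0.78,0.4066
Pure error,2.90,,3.20,,11.16,,4.32,
Total,106.48,,120.64,,178.62,,148.20,
R2,0.964,,0.969,,0.936,,0.966,
R2_adj,0.948,,0.955,,0.907,,0.950,
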