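sample,response,X1,X2,X3
C1,TPC,80.0,40,80.0
C1,AA,50.0,55,80.0
C2,TPC,65.0,60,80.0
C2,AA,57.5,40,80.0
C3,TPC,80.0,40,77.5
C3,AA,65.0,40,70.0
C4,TPC,80.0,40,80.0
C4,AA,80.0,50,77.5
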