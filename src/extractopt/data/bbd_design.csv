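run,x1_coded,x2_coded,x3_coded,X1,X2,X3
1,-1,-1,0,50,40,75
2,1,-1,0,80,40,75
3,-1,1,0,50,60,75
4,1,1,0,80,60,75
5,-1,0,-1,50,50,70
6,1,0,-1,80,50,70
7,-1,0,1,50,50,80
8,1,0,1,80,50,80
9,0,-1,-1,65,40,70
10,0,1,-1,65,60,70
11,0,-1,1,65,40,80
12,0,1,1,65,60,80
13,0,0,0,65,50,75
14,0,0,0,65,50,75
15,0,0,0,65,50,75
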