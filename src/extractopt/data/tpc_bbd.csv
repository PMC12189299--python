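run,C1_exp,C1_pred,C2_exp,C2_pred,C3_exp,C3_pred,C4_exp,C4_pred
1,326 ± 2,324,234 ± 1,234,226 ± 3,227,257 ± 1,256
2,340 ± 4,343,228 ± 1,229,234 ± 4,233,288 ± 4,285
3,326 ± 1,323,248 ± 3,247,230 ± 4,231,278 ± 1,281
4,323 ± 6,324,256 ± 3,255,233 ± 1,232,259 ± 4,259
5,291 ± 6,292,235 ± 1,235,219 ± 5,218,265 ± 1,263
6,294 ± 3,292,256 ± 1,259,221 ± 4,222,260 ± 2,260
7,344 ± 2,346,264 ± 1,260,227 ± 2,226,253 ± 1,253
8,368 ± 5,366,241 ± 2,240,229 ± 1,230,262 ± 1,264
9,286 ± 8,286,250 ± 3,249,205 ± 1,205,265 ± 2,268
10,302 ± 1,302,267 ± 1,266,206 ± 3,206,277 ± 6,277
11,377 ± 2,376,249 ± 1,250,212 ± 1,212,275 ± 2,275
12,340 ± 3,340,270 ± 2,271,214 ± 2,214,267 ± 2,264
13,330 ± 1,330,252 ± 4,252,208 ± 1,208,221 ± 1,221
14,330 ± 1,330,252 ± 4,252,208 ± 1,208,221 ± 1,221
15,330 ± 1,330,252 ± 4,252,208 ± 1,208,221 ± 1,221
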