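patient_id,nodal_pct,osseous_pct,prostate_pct,composite_pct,psa_pct
1,-100,NA,-100,-100,-100
2,NA,14,-100,-97,-100
3,NA,NA,-100,-100,-84
4,-66,NA,-100,-70,-99
5,-100,-47,-100,-100,-100
6,NA,-87,-100,-89,-100
7,NA,NA,-100,-100,-92
8,-100,NA,-100,-100,-95
9,-62,NA,-100,-94,-92
10,-100,-100,-100,-100,-100
11,-100,-75,NA,-76,-100
12,-20,NA,NA,-20,NA
13,87,-45,-100,31,-69
14,-96,-62,-100,-70,-100
15,NA,-35,-100,-98,-83
16,-100,-80,-41,-49,-98
17,-100,-100,NA,-100,-100
18,NA,-100,-100,-100,-100
19,-100,-100,-100,-100,-100
20,NA,NA,-100,-100,-100
21,-100,-64,-100,-98,-100
22,-100,-100,-100,-100,-100
23,-100,-100,-100,-100,-100
24,-100,-100,-100,-100,-100
25,NA,-100,-100,-100,-100
26,-100,-100,-95,-98,-99
27,NA,-100,-95,-95,-100
28,-59,NA,NA,-59,-100
29,-100,NA,-100,-100,-100
30,-100,NA,-52,-56,-97
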