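patient_id,disease_timing,mitnm_at_diagnosis,prostate_bed_disease,regional_nodal_disease,nonregional_nodal_disease,osseous_disease,interval_months,interval_treatment,psa_pct_reduction
1,De novo,T3bN1bM0,Yes,Yes,No,No,30,ADT + radiotherapy,100
2,De novo,T2mN0M1b,Yes,No,No,Yes,14,Surgery + ADT + radiotherapy,100
3,De novo,T2uN0M0,Yes,No,No,No,13,Surgery,84
4,Recurrence,T2mN1bM0,Yes,Yes,No,No,10,ADT + radiotherapy,99
5,De novo,T2mN1bM1b,Yes,Yes,No,Yes,21,ADT + radiotherapy,100
6,Recurrence,T2mN0M1b,Yes,No,No,Yes,3,ADT + radiotherapy,100
7,De novo,T2mN1aM0,Yes,Yes,No,No,3,Surgery,92
8,De novo,T3bN1aM1a,Yes,Yes,Yes,No,20,Surgery + ADT + radiotherapy,95
9,De novo,T3bN1bM1a,Yes,Yes,Yes,No,21,Surgery + ADT,92
10,De novo,T3aN1aM1b,Yes,Yes,No,Yes,11,ADT + radiotherapy,100
11,Recurrence,T0N0M1b,No,No,Yes,Yes,12,ADT + radiotherapy,100
12,Recurrence,T0N1aM0,No,Yes,No,No,12,Unknown,NA
13,De novo,T3bN1bM1b,Yes,Yes,Yes,Yes,4,ADT,69
14,De novo,T3bN1bM1b,Yes,Yes,No,Yes,5,ADT + radiotherapy,100
15,De novo,T3bN0M1b,Yes,Yes,Yes,Yes,7,ADT + radiotherapy,83
16,De novo,T3bN1bM1b,Yes,Yes,No,Yes,7,ADT + radiotherapy,98
17,Recurrence,TrN1bM1b,Yes,Yes,No,Yes,15,ADT + radiotherapy,100
18,De novo,T2uN1aM1b,Yes,Yes,No,Yes,26,Surgery + ADT + radiotherapy,100
19,De novo,T3bN1bM1b,Yes,Yes,No,Yes,7,ADT + radiotherapy,100
20,De novo,T2mN1aM1b,Yes,Yes,No,Yes,7,ADT + radiotherapy,100
21,De novo,T3bN1aM1b,Yes,Yes,No,Yes,7,ADT + radiotherapy,100
22,De novo,T2mN1aM0,Yes,Yes,No,No,7,ADT + radiotherapy,100
23,De novo,T2mN1bM1a,Yes,Yes,Yes,No,7,ADT + radiotherapy,100
24,De novo,T3bN1bM1b,Yes,Yes,No,Yes,18,ADT + radiotherapy,100
25,De novo,T2mN0M1b,Yes,No,No,Yes,9,ADT + radiotherapy,100
26,De novo,T2mN1aM0,Yes,Yes,No,Yes,6,ADT + radiotherapy,99
27,De novo,T2mN0M1b,Yes,No,No,Yes,7,ADT + radiotherapy,100
28,Recurrence,T0N1bM1a,No,Yes,Yes,No,7,ADT,100
29,De novo,T2mN1bM1a,Yes,Yes,Yes,No,8,ADT + radiotherapy,100
30,De novo,T2mN1bM1a,Yes,Yes,Yes,No,7,ADT + radiotherapy,97
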