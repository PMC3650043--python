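patient_id,entry,exit,event,female,hba1c
0,0.0,4.0,0,1,8.11
1,0.0,2.908928,1,0,6.06
2,0.0,0.896119,1,0,8.74
3,0.0,1.394346,1,0,8.28
4,0.0,4.0,0,1,6.19
5,0.0,3.281094,1,0,8.08
6,0.0,2.888817,1,1,6.77
7,0.0,2.22513,1,0,6.85
8,0.0,0.849455,1,0,6.37
9,0.0,1.166857,1,0,7.56
10,0.0,1.96587,1,0,6.05
11,0.0,0.15913,1,1,8.53
12,0.0,1.437317,1,1,6.82
13,0.0,0.963973,1,0,7.83
14,0.0,4.0,0,1,4.48
15,0.0,0.548987,1,0,8.9
16,0.0,1.885111,1,1,6.02
17,0.0,1.184991,1,0,6.84
18,0.0,1.506906,1,1,7.72
19,0.0,1.785086,1,1,7.98
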