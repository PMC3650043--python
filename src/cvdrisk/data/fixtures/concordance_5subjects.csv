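patient_id,score,time,event
0,0.82,1.0,1
1,0.3,4.5,0
2,0.55,2.0,1
3,0.55,3.0,0
4,0.1,5.0,1
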