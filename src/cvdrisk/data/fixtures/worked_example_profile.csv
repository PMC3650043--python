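female,age_at_diagnosis,diabetes_duration,hba1c,systolic_bp,diastolic_bp,ldl,tc_hdl_ratio,bmi,smoker,macroalbuminuria,microalbuminuria,ami_history,hf_history,stroke_history,naihd_history,ami_since_diagnosis,hf_since_diagnosis,stroke_since_diagnosis,naihd_since_diagnosis,duration_at_first_event
0,48.0,10.0,8.0,150.0,80.0,2.0,4.3,28.0,0,1,0,0,0,0,0,0,0,0,0,10.0
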