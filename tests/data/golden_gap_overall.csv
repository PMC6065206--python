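level,observed_pct,predicted_pct,diff_pp,additional_raw,additional_patients,one_in_n
claims_only,25.0,50.0,25.0,3.0,0,2
plus_problem_list,41.666667,50.0,8.333333,1.0,0,6
plus_clinical,58.333333,50.0,-8.333333,-1.0,0,
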