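level,observed_pct,predicted_org_pct,predicted_org_ci_low_pct,predicted_org_ci_high_pct,predicted_ref_pct,predicted_ref_ci_low_pct,predicted_ref_ci_high_pct
claims_only,29.1,33.2,33.2,33.3,38.5,38.5,38.6
plus_problem_list,30.0,33.9,33.9,34.0,38.5,38.5,38.6
plus_clinical,36.0,39.5,39.5,39.5,38.5,38.5,38.6
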