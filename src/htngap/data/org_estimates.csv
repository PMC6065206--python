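org_id,observed_claims_pct,predicted_claims_pct,observed_claims_pl_pct,predicted_claims_pl_pct,observed_all_pct,predicted_all_pct,predicted_reference_pct
1,35.4,40.1,37.8,41.4,46.1,47.6,46.2
2,34.9,38.5,35.5,38.9,44.3,44.6,43.9
3,34.6,39.0,37.0,39.3,40.4,42.4,40.7
4,34.2,34.2,35.4,35.0,41.0,40.0,38.2
5,31.9,32.4,32.3,33.3,39.3,40.4,37.9
6,31.8,33.6,32.6,34.3,40.7,40.1,38.0
7,31.4,34.2,31.4,35.0,38.5,41.1,40.8
8,30.5,31.5,30.7,32.2,34.9,36.8,36.1
9,30.1,35.9,31.5,36.7,37.5,42.2,40.6
10,29.6,35.0,30.9,35.3,38.5,39.8,39.1
11,28.9,31.1,29.9,31.7,36.8,38.6,36.3
12,28.6,32.5,29.2,33.3,33.8,38.4,37.9
13,28.5,32.6,29.8,33.5,34.7,39.3,38.1
14,28.4,32.3,29.9,32.9,39.3,40.0,38.4
15,28.4,34.0,32.9,34.9,37.3,40.8,39.5
16,28.3,30.9,29.7,31.7,33.6,37.1,35.4
17,28.3,35.4,28.8,36.2,35.0,41.3,41.3
18,28.0,35.3,28.9,35.9,33.2,40.0,41.4
19,27.5,30.2,27.7,30.9,33.8,37.0,35.9
20,27.5,32.9,28.6,33.7,33.5,39.3,38.0
21,24.7,34.0,27.2,34.4,35.7,40.7,39.9
22,24.5,32.4,25.7,32.7,30.7,37.1,37.5
23,24.2,33.1,24.3,33.7,31.4,39.3,38.4
24,22.2,31.4,22.7,31.8,26.5,35.5,37.8
25,17.1,31.8,18.3,32.2,24.2,38.0,38.2
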