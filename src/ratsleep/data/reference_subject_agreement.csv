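subject,agreement_5stage_pct,kappa_5stage,agreement_3stage_pct,kappa_3stage
1,92.17,0.87,93.64,0.88
2,91.79,0.88,94.5,0.91
3,91.07,0.87,95,0.91
4,89.92,0.83,92.3,0.86
5,91.67,0.87,95.09,0.91
6,93.61,0.90,96.6,0.94
7,94,0.91,96.66,0.94
8,90.16,0.85,92.75,0.87
9,92.08,0.88,94.38,0.90
10,90.31,0.85,91.65,0.85
11,97.18,0.96,98.64,0.96
12,96.84,0.95,98.87,0.98
13,96.97,0.95,97.9,0.96
14,94.85,0.92,95.73,0.92
15,89.89,0.84,92.31,0.86
16,87.42,0.81,90.22,0.82
17,88.6,0.84,92,0.86
18,87.95,0.82,91.77,0.85
19,93.09,0.9,97.33,0.95
20,89.32,0.78,90.44,0.8
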