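study,or,ci_lower,ci_upper
1,1.11,0.51,2.39
2,0.97,0.78,1.21
3,1.13,0.73,1.72
4,1.08,0.42,2.75
5,0.88,0.39,1.95
6,1.28,0.71,2.30
7,1.19,0.69,2.08
8,3.82,1.37,10.6
9,1.06,0.63,1.79
10,2.95,1.54,5.63
11,2.36,1.18,4.72
12,1.68,1.05,2.70
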