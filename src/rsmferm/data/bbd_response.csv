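run,mean,se
1,1.54,0.12
2,2.03,0.02
3,1.48,0.01
4,1.84,0.06
5,1.98,0.08
6,2.08,0.03
7,1.99,0.13
8,1.65,0.01
9,1.95,0.02
10,2.09,0.03
11,2.09,0.09
12,2.05,0.01
13,1.97,0.03
14,2.07,0.04
15,2.08,0.01
16,2.08,0.11
17,2.10,0.08
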