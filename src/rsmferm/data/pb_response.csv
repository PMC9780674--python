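run,mean,se
1,1.75,0.01
2,1.43,0.04
3,1.61,0.01
4,1.64,0.03
5,1.54,0.01
6,1.40,0.04
7,1.93,0.06
8,1.58,0.06
9,1.63,0.04
10,1.77,0.01
11,1.72,0.06
12,1.73,0.08
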