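run,beef_broth,peptone,glucose,is_center
1,0,1,-1,0
2,0,0,0,1
3,-1,0,-1,0
4,0,-1,-1,0
5,-1,0,1,0
6,0,0,0,1
7,-1,1,0,0
8,1,0,-1,0
9,1,0,1,0
10,0,0,0,1
11,1,1,0,0
12,0,1,1,0
13,0,-1,1,0
14,0,0,0,1
15,0,0,0,1
16,1,-1,0,0
17,-1,-1,0,0
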