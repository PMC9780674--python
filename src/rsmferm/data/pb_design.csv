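run,beef_broth,peptone,yeast_extract,glucose,KH2PO4,MgSO4,is_center
1,1,1,1,-1,-1,-1,0
2,1,-1,1,1,-1,1,0
3,1,1,-1,1,1,1,0
4,-1,-1,1,-1,1,1,0
5,1,-1,-1,-1,1,-1,0
6,1,-1,1,1,1,-1,0
7,-1,1,1,-1,1,1,0
8,-1,-1,-1,1,-1,1,0
9,-1,1,1,1,-1,-1,0
10,1,1,-1,-1,-1,1,0
11,-1,-1,-1,-1,-1,-1,0
12,-1,1,-1,1,1,-1,0
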