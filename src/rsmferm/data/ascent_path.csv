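step,beef_broth,peptone,yeast_extract,glucose,KH2PO4,MgSO4,response_mean,response_se
1,20,0.1,0.15,1,0.2,0.02,2.09,0.03
2,30,0.3,0.15,2,0.2,0.02,2.17,0.06
3,40,0.5,0.15,3,0.2,0.02,2.06,0.06
4,50,0.7,0.15,4,0.2,0.02,2.02,0.04
5,60,0.9,0.15,5,0.2,0.02,1.75,0.11
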