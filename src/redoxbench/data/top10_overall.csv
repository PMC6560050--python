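rank,functional,family,hf_exchange_pct,mue,maxe,maxe_complex
1,BB1K,hm-GGA,42.00,1.72,4.47,Fe(H2O)5(CH3S-)
2,mPWB1K,hm-GGA,44.00,1.93,3.98,Fe(H2O)5(CH3S-)
3,mPW1B95,hm-GGA,31.00,2.28,6.02,Fe(H2O)3(HCOO-)
4,BMK,hm-GGA,42.00,2.49,3.93,Fe(H2O)5(HCOO-)
5,B3LYP,h-GGA,20.00,2.51,6.22,Fe(H2O)3(HCOO-)
6,B3PW91,h-GGA,20.00,2.72,7.23,Fe(H2O)3(HCOO-)
7,mPW1N,h-GGA,40.60,2.74,4.04,Fe(H2O)3(CH3S-)
8,M06-2X,hm-GGA,54.00,2.84,6.93,Fe(H2O)3(CH3O-)
9,mPW1K,h-GGA,42.80,3.03,4.30,Fe(H2O)3(CH3S-)
10,PBE1PBE,h-GGA,25.00,3.08,7.21,Fe(H2O)3(HCOO-)
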