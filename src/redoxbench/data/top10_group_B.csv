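rank,functional,family,hf_exchange_pct,mue,maxe,Fe(H2O)3(CH3O-),Fe(H2O)3(CH3S-),Fe(H2O)3(NH2CH3),Fe(H2O)3(HCOO-)
1,BMK,hm-GGA,42.00,2.02,3.71,3.71,-1.24,1.84,-1.30
2,B3LYP,h-GGA,20.00,2.10,6.22,0.02,-0.63,-1.55,-6.22
3,wB97X-D,h-GGA,22.20/100.00,2.33,4.21,-4.21,-0.82,0.38,-3.90
4,BB1K,hm-GGA,42.00,2.44,4.33,1.59,-4.33,0.93,-2.92
5,mPWB1K,hm-GGA,44.00,2.53,3.97,2.61,-3.97,1.61,-1.93
6,mPW1N,h-GGA,40.60,2.65,4.04,3.68,-4.04,2.59,-0.27
7,mPW1B95,hm-GGA,31.00,2.72,6.02,-0.69,-2.45,-1.71,-6.02
8,mPW1K,hm-GGA,44.00,2.96,4.30,4.22,-4.30,3.01,0.30
9,MN12-L,m-NGA,-,2.98,4.50,4.03,4.50,0.56,-2.84
10,M06-2X,hm-GGA,54.00,3.07,6.93,6.93,-2.52,2.21,0.63
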