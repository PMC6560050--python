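rank,functional,family,hf_exchange_pct,mue,maxe,Fe(H2O),Fe(H2O)2,Fe(H2O)4,Fe(H2O)6
1,BB1K,hm-GGA,42.00,0.67,1.76,-0.47,0.21,-0.26,1.76
2,mPWB1K,hm-GGA,44.00,0.99,1.93,0.44,1.28,0.29,1.93
3,mPW1N,h-GGA,40.60,2.23,3.49,1.21,2.55,1.68,3.49
4,BMK,hm-GGA,42.00,2.41,3.62,3.39,1.52,-1.10,3.62
5,mPW1B95,hm-GGA,31.00,2.49,4.12,-2.39,-4.12,-2.56,0.89
6,M06-2X,hm-GGA,54.00,2.53,4.50,4.50,3.79,0.89,0.93
7,mPW1K,h-GGA,42.80,2.62,3.51,1.70,3.30,1.98,3.51
8,MN12-SX,hm-NGA,25.00/-,2.98,7.43,0.81,-1.43,2.25,7.43
9,B3LYP,h-GGA,20.00,3.03,5.41,-0.67,-5.41,-2.61,3.42
10,mPW2PLYP,hh-GGA,55.00,3.08,4.69,-3.55,-1.89,-4.69,-2.19
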