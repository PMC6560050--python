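rank,functional,family,hf_exchange_pct,mue,maxe,Fe(H2O)5(CH3O-),Fe(H2O)5(CH3S-),Fe(H2O)5(NH2CH3),Fe(H2O)5(HCOO-)
1,mPW1B95,hm-GGA,31.00,1.65,3.26,-1.73,-3.26,0.86,0.74
2,PBE1PBE,h-GGA,25.00,1.71,3.48,-2.51,-3.48,-0.61,-0.25
3,B3PW91,h-GGA,20.00,1.73,2.60,-2.06,-2.60,1.23,1.02
4,wB97X-D,h-GGA,22.20/100.00,1.99,3.43,0.38,0.77,3.43,3.39
5,BB1K,hm-GGA,42.00,2.03,4.47,0.23,-4.47,1.68,1.76
6,mPWB1K,hm-GGA,44.00,2.29,3.98,1.05,-3.98,1.92,2.20
7,B3LYP,h-GGA,20.00,2.38,3.22,-0.41,-3.08,3.22,2.82
8,B1LYP,h-GGA,25.00,2.81,7.23,-2.53,-7.23,0.90,0.57
9,B97-1,h-GGA,21.00,2.82,4.10,-3.38,-4.10,-0.35,-3.46
10,M06-2X,hm-GGA,54.00,2.91,4.77,4.77,-2.43,1.39,3.05
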