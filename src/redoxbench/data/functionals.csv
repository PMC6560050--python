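functional,family
SPW91,LDA
SVWN,LDA
BP86,GGA
BPBE,GGA
BPW91,GGA
G96LYP,GGA
HCTH407,GGA
OLYP,GGA
OPL,GGA
M06-L,m-GGA
M11-L,m-GGA
mPWB95,m-GGA
OTPSS,m-GGA
VSXC,m-GGA
B1LYP,h-GGA
B3LYP,h-GGA
B3P86,h-GGA
B3PW91,h-GGA
B97-1,h-GGA
B97-2,h-GGA
B97-D3,h-GGA
BhandH,h-GGA
mPW1K,h-GGA
mPW1N,h-GGA
PBE1PBE,h-GGA
wB97X-D,h-GGA
BB1K,hm-GGA
BMK,hm-GGA
M05,hm-GGA
M05-2X,hm-GGA
M06,hm-GGA
M06-2X,hm-GGA
M11,hm-GGA
mPW1B95,hm-GGA
mPWB1K,hm-GGA
TPSSh,hm-GGA
B2GPPLYP,hh-GGA
B2PLYP,hh-GGA
DSD-BLYP,hh-GGA
mPW2PLYP,hh-GGA
N12,NGA
MN12-L,m-NGA
MN12-SX,hm-NGA
OVWN5,GGE
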