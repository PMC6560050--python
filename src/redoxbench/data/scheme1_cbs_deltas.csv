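complex_id,cbs,diff_dz,diff_tz,diff_qz
Fe(H2O),-602.8804,-6.23,-3.75,-1.12
Fe(H2O)2,-538.3929,-6.10,-3.74,-1.23
Fe(H2O)4,-442.5902,-6.05,-3.68,-1.35
Fe(H2O)6,-386.9860,-5.64,-3.44,-1.09
Fe(H2O)3(CH3O-),-279.0221,-7.19,-4.11,-2.09
Fe(H2O)3(CH3S-),-263.8079,-5.02,-2.56,-1.08
Fe(H2O)3(NH2CH3),-425.3816,-6.66,-3.73,-1.39
Fe(H2O)3(HCOO-),-307.3227,-6.54,-3.86,-1.76
Fe(H2O)5(CH3O-),-252.6365,-6.56,-3.93,-1.97
Fe(H2O)5(CH3S-),-241.5428,-4.96,-2.58,-1.07
Fe(H2O)5(NH2CH3),-376.6431,-6.22,-3.53,-1.15
Fe(H2O)5(HCOO-),-274.9742,-5.90,-3.60,-1.53
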