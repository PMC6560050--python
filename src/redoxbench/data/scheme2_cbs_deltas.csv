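complex_id,cbs,diff_scheme1,diff_qz
Fe(H2O),-602.8540,-0.0264,-1.0956
Fe(H2O)2,-538.2482,-0.1447,-1.0813
Fe(H2O)4,-442.1297,-0.4605,-0.8882
Fe(H2O)6,-386.5973,-0.3887,-0.7042
Fe(H2O)3(CH3O-),-277.7082,-1.3139,-0.7751
Fe(H2O)3(CH3S-),-263.7248,-0.0830,-0.9939
Fe(H2O)3(NH2CH3),-424.9332,-0.4484,-0.9379
Fe(H2O)3(HCOO-),-306.5217,-0.8010,-0.9611
Fe(H2O)5(CH3O-),-251.2897,-1.3468,-0.6250
Fe(H2O)5(CH3S-),-241.3777,-0.1651,-0.9084
Fe(H2O)5(NH2CH3),-376.2997,-0.3434,-0.8075
Fe(H2O)5(HCOO-),-274.2278,-0.7464,-0.7799
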