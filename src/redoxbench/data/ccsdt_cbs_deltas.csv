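complex_id,ccsdt_cbs,mp2_cbs,diff
Fe(H2O),-593.8053,-602.8540,9.05
Fe(H2O)2,-532.2488,-538.2482,6.00
Fe(H2O)4,-437.8827,-442.1297,4.25
Fe(H2O)6,-383.3053,-386.5973,3.29
Fe(H2O)3(CH3O-),-268.8103,-277.7082,8.90
Fe(H2O)3(CH3S-),-263.1074,-263.7248,0.62
Fe(H2O)3(NH2CH3),-419.8000,-424.9332,5.13
Fe(H2O)3(HCOO-),-302.7982,-306.5217,3.72
Fe(H2O)5(CH3O-),-242.1318,-251.2897,9.16
Fe(H2O)5(CH3S-),-239.3788,-241.3777,2.00
Fe(H2O)5(NH2CH3),-372.7251,-376.2997,3.57
Fe(H2O)5(HCOO-),-268.0456,-274.2278,6.18
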