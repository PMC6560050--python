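complex_id,dz,tz,qz
Fe(H2O),-596.6545,-599.1266,-601.7583
Fe(H2O)2,-532.2910,-534.6568,-537.1668
Fe(H2O)4,-436.5451,-438.9066,-441.2415
Fe(H2O)6,-381.3428,-383.5432,-385.8931
Fe(H2O)3(CH3O-),-271.8354,-274.9105,-276.9331
Fe(H2O)3(CH3S-),-258.7914,-261.2471,-262.7309
Fe(H2O)3(NH2CH3),-418.7231,-421.6494,-423.9952
Fe(H2O)3(HCOO-),-300.7855,-303.4670,-305.5606
Fe(H2O)5(CH3O-),-246.0797,-248.7022,-250.6648
Fe(H2O)5(CH3S-),-236.5792,-238.9616,-240.4693
Fe(H2O)5(NH2CH3),-370.4211,-373.1151,-375.4922
Fe(H2O)5(HCOO-),-269.0788,-271.3712,-273.4479
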