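table,statistic,column,value
scheme1_cbs_deltas,MSE,diff_dz,-6.09
scheme1_cbs_deltas,MSE,diff_tz,-3.54
scheme1_cbs_deltas,MSE,diff_qz,-1.40
scheme1_cbs_deltas,MUE,diff_dz,6.09
scheme1_cbs_deltas,MUE,diff_tz,3.54
scheme1_cbs_deltas,MUE,diff_qz,1.40
scheme2_cbs_deltas,MSE,diff_scheme1,-0.52
scheme2_cbs_deltas,MSE,diff_qz,-0.88
scheme2_cbs_deltas,MUE,diff_scheme1,0.52
scheme2_cbs_deltas,MUE,diff_qz,0.88
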