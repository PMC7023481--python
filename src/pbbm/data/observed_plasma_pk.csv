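parameter,observed
cmax_ug_per_ml,41.7
tmax_h,3.00
auc_0_inf_ug_h_per_ml,259
auc_0_28h_ug_h_per_ml,255
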