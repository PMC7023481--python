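medium,ph,solubility_mg_per_ml
fasted_human_gastric_fluid,1.46,0.0048
fasted_human_duodenal_fluid,3.74,0.0102
fasted_human_jejunal_fluid,4.6,1.2
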