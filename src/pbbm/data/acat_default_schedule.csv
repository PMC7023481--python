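compartment,time_h,volume_ml,ph,transit_time_h
stomach,0.0,48.92,1.3,0.25
duodenum,0.0,44.57,6.0,0.26
jejunum1,0.0,166.6,6.2,0.94
jejunum2,0.0,131.0,6.4,0.75
ileum1,0.0,102.0,6.6,0.58
ileum2,0.0,75.35,6.9,0.42
ileum3,0.0,53.57,7.4,0.29
caecum,0.0,50.49,6.4,4.48
asc_colon,0.0,53.55,6.8,13.44
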