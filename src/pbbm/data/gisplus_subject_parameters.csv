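subject,kempt_per_h,k_td_per_h,k_tj_per_h,k_diss_ml_per_ug_h,v1_ml,v2_ml
B003V1,0.39,0.20,0.130,0.101,80.4,20.0
B004V1,0.08,0.59,0.059,1.48e-3,73.9,18.5
B004V2,0.02,1.86,0.209,5.05e-3,195.4,209.2
B005V1,0.51,0.22,0.010,1.61e-4,15.3,2.5
B005V2,0.18,0.45,0.224,3.62e-4,350.5,84.5
B006V1,0.95,1.84,0.042,3.51e-4,123.2,64.6
B017V1,0.16,0.41,0.081,5.75e-3,62.8,10.2
B017V2,0.07,0.08,0.036,1.11e-3,77.6,19.5
B042V1,0.13,10.26,0.000,7.31e-2,29.0,5.2
B042V2,0.05,0.19,0.086,1.52e-3,150.0,80.6
B049V1,0.05,0.19,0.086,1.52e-3,262.3,10.6
B049V2,0.05,0.19,0.086,1.52e-3,150.0,80.6
B052V1,2.79,2.99,0.019,6.96e-4,19.0,27.6
B053V1,1.24,1.79,0.039,3.48e-4,137.8,215.8
B055V1,4.05,0.47,0.100,9.00e-5,126.6,50.0
B055V2,3.65,0.07,0.001,4.33e-4,119.6,93.4
B063V1,1.00e-3,4.12,1.140,1.96e-3,115.9,56.3
B065V1,0.20,2.51,0.092,0.121,500.0,283.1
B065V2,1.28,9.48,0.002,1.59,357.7,10.1
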