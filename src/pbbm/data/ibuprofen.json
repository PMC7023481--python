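{
  "name": "ibuprofen",
  "molecular_weight_g_per_mol": 206.29,
  "pka_acidic": 4.54,
  "logp": 3.65,
  "peff_cm_per_s": 4.1e-4,
  "particle_radius_um": 62.0,
  "dose_mg": 800.0,
  "dose_volume_ml": 250.0,
  "reference_ph": 6.2,
  "reference_solubility_mg_per_ml": 1.99,
  "two_compartment_pk": {
    "k10_per_h": 1.16,
    "k12_per_h": 4.55,
    "k21_per_h": 3.46,
    "clearance_l_per_h": 4.05,
    "infusion_duration_h": 0.1
  },
  "acat_defaults": {
    "gastric_transit_h_static": 0.25,
    "gastric_transit_h_dynamic": 2.04,
    "true_density_g_per_ml": 1.2,
    "diffusion_coeff_cm2_per_s": 7.5e-6
  }
}
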