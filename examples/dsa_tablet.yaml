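# Weakly basic drug (tosylate salt) in an immediate-release tablet,
# USP apparatus II, 900 mL pH 4.5 acetate buffer.
compound:
  name: DS-A
  ionization: monoprotic_base
  pKa: 7.6
  intrinsic_solubility_ug_ml: 0.15
  true_density_g_ml: 1.3
  diffusion_coefficient_cm2_s: 8.0e-6
  molecular_weight_g_mol: 450.0
salt:
  counterion_pKa: -1.0
  counterion_stoichiometry: 1
  salt_solubility_mg_ml: 1.8
  conversion_lag_min: 3.0
medium:
  name: pH45-acetate-50mM
  volume_ml: 900.0
  bulk_pH: 4.5
  buffer_species: [[4.76, 50.0]]
  surfactant_class: none
psd:
  median_diameter_um: 30.0
  geometric_sd: 1.8
  n_points: 200
  seed: 7
  n_bins: 20
dosage_form:
  kind: tablet
  mass_mg: 400.0
  solid_fraction: 0.85
  true_density_g_ml: 1.25
  aspect_ratios: [0.6, 0.35]
  penetration_velocity_mm_min: {none: 0.5, surfactant: 0.9}
  wetting_time_min: 2.0
dose_mg: 12.0
t_end_min: 60.0
t_step_min: 1.0
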