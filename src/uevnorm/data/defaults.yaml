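# Default calibration of the synthetic cohort / rat-study generator.
# Human arm: sex-stratified total kidney volume (ml), creatinine
# excretion (mmol/day), kidney function (ml/min); uEV excretion is
# kappa x TKV with lognormal noise. Rat arm: group sizes, kidney weight
# at uninephrectomy (g), FITC-sinistrin GFR (ml/min) and the group
# effect factors. Any field may be overridden in a user config file.
seed: 0
n_donors: 19
sex_ratio_female: 0.631578947368421
tkv_mean: {M: 351.0, F: 300.0}
tkv_sd: {M: 37.0, F: 57.0}
kidney_split_sd: 0.03
creat_excretion_mean: {M: 17.1, F: 9.0}
creat_excretion_sd: {M: 1.3, F: 2.6}
egfr_mean: {M: 99.0, F: 89.0}
egfr_sd: {M: 18.0, F: 25.0}
creat_clearance_mean: {M: 128.0, F: 99.0}
creat_clearance_sd: {M: 7.0, F: 33.0}
uev_per_nephron_mass: 1.225e+8        # uEVs/day per ml TKV (male)
female_kappa_scale: 0.599            # female per-ml rate relative to male
uev_noise_sd: 0.30
measurement_noise_sd: 0.10
spot_flow_median: 1.5                # L/day equivalent flow at the spot void
spot_flow_sigma: 0.4
urine_volume_mean: 2.0               # L per 24-h collection
urine_volume_sd: 0.75
nephrectomy_fraction_removed: 0.5
h_proximal: 2.0                      # proximal (CD9-) hypertrophy, fold
h_distal: 1.4                        # distal (CD9+) hypertrophy, fold
cd9_pos_fraction: 0.6
egfr_post_factor_mean: 0.64
egfr_post_factor_sd: 0.10
rat:
  n_per_group: {sham: 10, UNX: 8, 5/6NX: 8}
  kidney_weight_mean: 1.2
  kidney_weight_sd: 0.1
  gfr_mean: 3.2
  gfr_sd: 0.6
  gfr_change_factor: {sham: 1.54, UNX: 1.16, 5/6NX: 0.39}
  gfr_noise_sd: 0.10
  uev_excretion_mean: 7.5e+11
  uev_excretion_sd: 1.3e+11
  hypertrophy_factor: {sham: 1.0, UNX: 1.4, 5/6NX: 4.0}
  sham_growth_factor: 1.4
  sham_uev_growth: 1.33
  kidney_fraction: {sham: 1.0, UNX: 1.0, 5/6NX: 0.3333333333333333}
  nephron_fraction: {sham: 1.0, UNX: 0.5, 5/6NX: 0.16666666666666666}
  body_weight_gain_mean: {sham: 183.0, UNX: 186.0, 5/6NX: 145.0}
  body_weight_gain_sd: 21.0
  weight_noise_sd: 0.05
  uev_noise_sd: 0.08
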