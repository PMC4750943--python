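medium_G: 25.0
medium_O: 0.07
model:
  variant: 4
  delta_L: 3.0
  ecm_min: 0.003
  p_oxyglc: 0.1
  p_atp_min: 900.0
  L_max: 20.0
  hill_n: 2
  W_max: 0.0005
  O_min: 0.08
  n_exp_max: 2.0
  k_div_max: null
  k_nec_max: 0.1
  nec_combination: noisy_or
  exposure_absolute_time: false
  deterministic_pdiv: false
cycle:
  m_d: 10
  m_g: 5
  tau: 18.0
  k_re: 0.0
  p_re: 0.0
  k_apt: 0.0
  k_lys: 0.01
  migration_D: 0.0
  migration_mode: unbiased
  adhesion_J: 0.0
  push_range: 30
metabolic:
  k_G_G: 0.068
  k_G_O2: 0.031
  k_O2_O2: 0.031
  k_O2_G: 0.1
  q_G_min: 186.67
  q_G_max: 706.67
  q_O2_min: 120.0
  q_O2_max: 306.66
  G_crit: 0.01
  atp_per_glycolysis: 2.0
  atp_per_o2: 5.666666666666667
  lactate_per_glucose: 2.0
  cell_volume: 2700.0
  lactate_printed_form: false
diffusion:
  D_tum:
    G: 250000.0
    O: 3600000.0
    L: 250000.0
    ECM: 1.0
    W: 180000.0
  medium_ratio: 30.0
  k_gen_ECM: 0.0012
  k_deg_ECM: 0.012
  k_gen_W: 5.0
  k_upt_W: 0.05
  ecm_steady: false
n_per_dim: 34
spacing: 16.8
jitter: 0.25
initial_cells: 1000
t_end: 156.0
field_interval: 1.5
output_interval: 24.0
record_profiles: true
profile_bin_width: 16.8
initial_tissue_age: 48.0
solver_tol: 1.0e-05
linear_solver: bicgstab
seed: 0
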