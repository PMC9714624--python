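adex:
  C: 150.0
  E_L: -70.0
  E_e: 0.0
  E_i: -85.0
  V_T: -50.0
  V_r: -52.0
  a_sub: 10.0
  b_spike: 132.0
  dt: 0.01
  eta: 2.0
  g_L: 10.0
  tau_exc: 3.0
  tau_inh: 20.0
  tau_q_input: 60.0
analysis:
  analysis_dt: 1.0
  hysteresis: 5.0
  lead_time: 10.0
  rate_sigma: 4.0
  savgol_order: 2
  savgol_window: 15
  vel_threshold: 20.0
controller:
  B_E: 60.0
  B_H: 20.0
  T_E1: 200.0
  T_E2: 20.0
  T_H1: 250.0
  T_H2: 150.0
  beta_omr: 0.03
  delay_amp_slope: 0.72
  delay_base: 70.0
  dt_ctrl: 0.1
  efferent_delay: 10.0
  fixation_tau: 200.0
  gh_slope: 0.05
  head_damping: 5.0
  horizon: 2000.0
  off_threshold: 0.2
  omr_bound: 30.0
  onset_threshold: 1.0
  vor_slope: 0.03
efferent:
  A: 3.0
  B_u: 1.4
  kappa: 0.0024696719199583553
input:
  I0: 14000.0
  beta_rate: 37.0
  gamma_shape: 3.0
  sigma_pop: 0.64
  u_T: 2.5
motor_map:
  e0_max: 40.0
  e0_min: -40.0
  gain_offset: 0.018
  gain_slope: -0.005
  map_length: 5.0
  n_units: 200
  s_coeff: 0.04
  sigma_exc: 0.3
  sigma_inh: 0.15
  tau_max: 60.0
  tau_min: 30.0
  w_exc_bar: 0.16
  w_ff_max: 10.0
  w_ff_min: 4.0
  w_inh_bar: 1.15
schema_version: 1
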