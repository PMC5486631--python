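# Reference scenario: every key at its default value.
# Any subset of these keys may appear in a user config; omitted keys keep
# the defaults shown here. Unknown keys are rejected.
blood:
  c_b: 4200.0
  rho_b: 1000.0
  t_b: 37.0
conductivity:
  alpha: 0.015
  e_threshold: 80000.0
  t_ref: 37.0
geometry:
  active_length: 0.006
  electrode_spacing: 0.0054
  liver_diameter: 0.1
  liver_height: 0.1
  needle_diameter: 0.001
  tumor_center:
  - 0.0
  - 0.0
  - 0.05
  tumor_diameter: 0.01
initial_temperature: 37.0
materials:
  electrode:
    cp: 450.0
    k: 18.0
    omega_b: 0.0
    q_met: 0.0
    rho: 7010.0
    sigma_base: 100000000.0
    sigma_porated: 100000000.0
  insulation:
    cp: 840.0
    k: 0.026
    omega_b: 0.0
    q_met: 0.0
    rho: 6450.0
    sigma_base: 1.0e-05
    sigma_porated: 1.0e-05
  liver:
    cp: 3540.0
    k: 0.52
    omega_b: 0.0005
    q_met: 4200.0
    rho: 1080.0
    sigma_base: 0.067
    sigma_porated: 0.241
  tumor:
    cp: 4180.0
    k: 0.6
    omega_b: 0.002
    q_met: 42000.0
    rho: 1220.0
    sigma_base: 0.135
    sigma_porated: 0.426
protocol:
  burst_length: 100.0
  burst_rate: 1.0
  n_bursts: 1
  pulse_width: 500.0
  rep_rate: 1000.0
  voltage: 4000.0
solver:
  cg_maxiter: 20000
  cg_rtol: 1.0e-08
  dt_burst: 1.0e-08
  dt_burst_averaged: 1.0e-06
  dt_cool: 0.001
  pennes_printed_sign: false
  porate_max_iter: 50
  refresh_dt: 1.0
  resolution:
    fine_margin: 0.0
    growth: 1.5
    h_coarse: 0.0025
    h_fine: 0.0005
    z_margin: 0.0
  t_final: 1.0
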