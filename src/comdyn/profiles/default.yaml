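# comdyn default parameter profile (schema v1)
# Sensorimotor constants: published reduced two-variable model values.
# Uncertainty/motor couplings: calibrated once against the behavioural
# test suite, then frozen here.  Units: nA, Hz, ms.
parameters:
  a: 270.0
  b: 108.0
  d: 0.154
  gamma: 0.641
  tau_s: 100.0
  J_N_self: 0.266
  J_N_cross: 0.065
  I0: 0.325
  J_A_ext: 0.00052
  mu0: 30.0
  J_mc0: 0.042
  tau_mc: 160.0
  J_V_inh: 0.021
  J_N_inh: 2.0
  mu_tonic: 2.4
  g_baseline: 1000.0
  g_reactivated: 3000.0
  tau_h: 300.0
  J_motor: 1.0
  J_N_LR: 1.0
  J_N_RL: 1.0
  T_pos: 750.0
  M_th: 17.4
  decision_threshold: 35.5
  sigma_noise: 0.011
  tau_noise: 14.0
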