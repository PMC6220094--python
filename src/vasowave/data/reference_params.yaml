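# vasowave reference parameter set v1 — units as documented in params.py
ip3:
  alpha: 2.8e-07
  K_Ca: 0.4
  k_a: 0.017
  k_d: 0.15
  delta: 0.001234
  G_prot_tot: 100000.0
  K_ATP: 0.025
  PIP2_tot: 50000000.0
  u_c: 1000000.0
  V_EC: 1.0e-12
  k_deg: 0.1
ec:
  F_ip3: 0.23
  K_r: 1.0
  B: 0.5
  c_b: 1.0
  C_cicr: 5.0
  s_c: 2.0
  c_c: 0.9
  D_extr: 0.24
  L: 0.025
  G_cat: 0.00066
  E_Ca: 50.0
  m3_cat: -0.18
  m4_cat: 0.37
  J0: 0.029
  G_tot: 6927.0
  v_K: -80.0
  a1: 53.3
  a2: 53.3
  b1: -80.8
  c1: -0.4
  m3b: 0.00132
  m4b: 0.3
  m3s: -0.28
  m4s: 0.389
  G_R: 955.0
  v_rest: -31.1
  C_m: 25.8
smc:
  F_ip3: 0.23
  K_r: 1.0
  G_Ca: 0.00129
  v_Ca1: 100.0
  v_Ca2: -24.0
  R_Ca: 8.5
  G_NaCa: 0.00316
  c_NaCa: 0.5
  v_NaCa: -30.0
  B: 2.025
  c_b: 1.0
  C_cicr: 55.0
  s_c: 2.0
  c_c: 0.9
  D_extr: 0.24
  v_d: -100.0
  R_d: 250.0
  L: 0.025
  gamma: 1970.0
  F_NaK: 0.0432
  G_Cl: 0.00134
  v_Cl: -25.0
  G_K: 0.00446
  v_K: -94.0
  lam: 45.0
  c_w: 0.0
  beta: 0.13
  v_Ca3: -27.0
  R_K: 12.0
  k_deg: 0.1
  C_m: 10.0
coupling:
  g_homo_smc: 1000.0
  g_homo_ec: 1000.0
  g_hetero: 50.0
  p_ca_homo_smc: 0.05
  p_ca_homo_ec: 0.05
  p_ca_hetero: 0.05
  p_ip3_homo_smc: 0.05
  p_ip3_homo_ec: 0.05
  p_ip3_hetero: 0.05
  z_ca: 2
  z_ip3: 0
  T: 293.0
  sigma: 1.0
  A_segment: 50.0
  dx: 0.8
  V_cell: 1.0e-12
phospho:
  v_p: 1.0
  W_T: 1.0
  K_1: 0.01
  K_2: 0.01
  V_MK: 2.5
  K_a: 0.5
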