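{
 "version": "1",
 "ep": {
  "g_Na": 14.838,
  "g_K1": 5.405,
  "g_to": 0.294,
  "g_Kr": 0.153,
  "g_Ks": 0.392,
  "p_KNa": 0.03,
  "g_CaL": 5e-05,
  "g_bNa": 0.00029,
  "g_bCa": 0.000592,
  "g_pCa": 0.1238,
  "k_pCa": 0.0005,
  "g_pK": 0.0146,
  "P_NaK": 2.724,
  "K_mK": 1.0,
  "K_mNa": 40.0,
  "k_NaCa": 1000.0,
  "gamma_NaCa": 0.35,
  "K_mCa": 1.38,
  "K_mNai": 87.5,
  "k_sat": 0.1,
  "alpha_NaCa": 2.5,
  "K_o": 5.4,
  "Na_o": 140.0,
  "Ca_o": 2.0,
  "C_myo": 185.0,
  "V_max_up": 0.009,
  "K_up": 0.00025,
  "V_leak": 0.00036,
  "V_xfer": 0.0038,
  "k_rel": 0.12,
  "ryr_ko_ca": 0.6,
  "ryr_ki_ca": 0.1,
  "ryr_kom": 0.06,
  "ryr_kim": 0.005,
  "ryr_ec50_sr": 1.5,
  "ryr_max_sr": 2.5,
  "ryr_min_sr": 1.0,
  "ryr_g_ig": 15.0,
  "ryr_k_load": 3.85,
  "ryr_k_cyt": 0.0015,
  "ryr_h_load": 20.0,
  "ryr_h_cyt": 4.0,
  "buf_c": 0.13,
  "K_buf_c": 0.001,
  "buf_sr": 10.0,
  "K_buf_sr": 0.3,
  "buf_ss": 0.4,
  "K_buf_ss": 0.00025,
  "V_c": 0.016404,
  "V_sr": 0.001094,
  "V_ss": 5.468e-05,
  "ical_mult": 1.0,
  "ikr_mult": 1.0,
  "iks_mult": 1.0,
  "serca_mult": 1.0
 },
 "mech": {
  "A_tot": 70.0,
  "a_on": 40.0,
  "k_off0": 0.12,
  "k_A": 0.01,
  "pi_min": 0.1,
  "k_N": 6.0,
  "k_on_xb": 0.12,
  "k_off_xb": 0.04,
  "xb_v_sens": 1000.0,
  "perm_exp": 1.6,
  "F_xb_max": 3.0,
  "v_max": 0.0015,
  "hill_a": 0.35,
  "p_len_max": 1.5,
  "len_b": 0.0002,
  "ov_s0": 0.6,
  "ov_s1": 0.92,
  "alpha_PE": 15.0,
  "beta_PE": 0.01,
  "alpha2fb": 15.0,
  "beta2fb": 0.01,
  "alpha_SE": 60.0,
  "beta_SE": 0.04,
  "alpha_XSE": 200.0,
  "beta_XSE": 0.05,
  "mu_VS1": 10.0,
  "mu_VS2": 5.0,
  "block_slack": 0.76,
  "L_max_um": 2.23,
  "F_norm": 1.32827
 },
 "fb": {
  "C_mf": 6.3,
  "g_Kv": 0.25,
  "g_K1": 0.4822,
  "I_NaK_max": 2.002,
  "K_mK": 1.0,
  "K_mNa": 11.0,
  "V_rev_NaK": -150.0,
  "B_NaK": -200.0,
  "g_bNa": 0.0095,
  "K_i": 129.4349,
  "Na_i": 8.5547,
  "K_o": 5.4,
  "Na_o": 140.0,
  "g_max": 8.0,
  "a_slope": 8.0,
  "V_rev_lo": -38.0,
  "V_rev_hi": -30.0,
  "length_lo": 0.8,
  "length_hi": 0.9,
  "stretch_rev_negative": true,
  "gmax_mult": 1.0,
  "vrev_mult": 1.0
 }
}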