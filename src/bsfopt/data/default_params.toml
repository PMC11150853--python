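k_y2act = 0.28
k_act2fert = 0.62
k_fert2old = 0.55
k_T_sum_min = 12.0
k_sum_y2act = 28.0
k_sum_ovi = 56.0
k_ovi = 5.9
k_mu = 0.0183
k_mu_old = 2.14
k_mu_ovi = 2.5
k_mu_N = 1.0
a1 = 0.986
a2 = 0.368
k_T_ovi_0 = -3.17
k_T_ovi_1 = 0.286
k_T_ovi_2 = -0.005
k_T_mu_0 = 3.13
k_T_mu_1 = -0.166
k_T_mu_2 = 0.0033
mu0 = -0.1
N_y0 = 50.0
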