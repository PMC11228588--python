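# Induction times of FDPNa3 anti-solvent crystallization, silent (no ultrasound).
# Columns as in the ultrasound table. Quirks preserved from the published table:
# the S=1.8 row prints ln t = 10.134 although ln(25200) = 10.1346 rounds to
# 10.135 (ln_t_printed_ok = 0); the S=1.95 row's published N_c is a typo
# ("2.1.55") and is stored as missing.
S,t_ind_s,T_K,ultrasound_W,ln_t_printed,ln_t_printed_ok,gamma_mJ_m2,N_c,dG_c_J_mol,r_c_nm
1.8,25200,298.15,0,10.134,0,4.578,3.160,1538.40,0.36
1.9,23400,298.15,0,10.060,1,4.578,2.427,1290.14,0.33
1.95,21960,298.15,0,9.996,0,4.578,,1191.73,0.32
2.0,21600,298.15,0,9.980,1,4.578,1.927,1106.27,0.31
2.1,18000,298.15,0,9.798,1,6.963,5.530,3398.02,0.44
2.2,16200,298.15,0,9.692,0,6.963,4.608,3008.87,0.41
2.3,12600,298.15,0,9.441,1,6.963,3.909,2696.28,0.39
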