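# Induction times of FDPNa3 anti-solvent crystallization, 100 W ultrasound bath.
# Columns beyond the measurement carry the published per-row CNT parameters for
# cross-checking: gamma (mJ/m^2), N_c, dG_c (J/mol), r_c (nm), and the published
# rounded ln t_ind. ln_t_printed_ok flags rows whose printed ln t matches
# round-half-even 3 d.p. of ln(t_ind_s).
S,t_ind_s,T_K,ultrasound_W,ln_t_printed,ln_t_printed_ok,gamma_mJ_m2,N_c,dG_c_J_mol,r_c_nm
1.8,19800,298.15,100,9.893,1,5.552,5.636,2743.888,0.44
1.9,15840,298.15,100,9.670,1,5.552,4.328,2301.089,0.41
1.95,15840,298.15,100,9.670,1,5.552,3.843,2125.567,0.39
2.0,14400,298.15,100,9.574,0,5.552,3.437,1973.126,0.37
2.1,12600,298.15,100,9.441,1,7.234,6.199,3809.599,0.46
2.2,10800,298.15,100,9.287,1,7.234,5.166,3373.318,0.43
2.3,9000,298.15,100,9.105,1,7.234,4.382,3022.863,0.41
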