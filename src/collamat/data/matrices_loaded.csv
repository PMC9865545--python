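# Matrix metadata, limiting case 1: neither TA nor CHDG released at equilibrium.
# Reference columns carry the published intermediate values for verification.
system,ta_pct,chdg_pct,rho_matrix,q_w,nu2eq_ref,cp_ref,delta_c_ref,dc_ref
Collagen,0,0,1.195,6.80,0.136,953,2.5,58
Collagen-TA(5%),5,0,1.245,5.66,0.155,1087,3.3,86
Collagen-TA(10%),10,0,1.290,4.30,0.196,1374,5.2,184
Collagen-TA(15%),15,0,1.316,4.11,0.198,1388,5.3,191
Collagen-TA(5%)-CHDG(9.09%),5,9.09,1.248,4.06,0.203,1423,5.6,208
Collagen-TA(10%)-CHDG(9.09%),10,9.09,1.285,4.02,0.196,1374,5.2,184
Collagen-TA(15%)-CHDG(9.09%),15,9.09,1.319,4.16,0.182,1276,4.5,144
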