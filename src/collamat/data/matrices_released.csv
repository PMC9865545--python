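# Matrix metadata, limiting case 2: TA and CHDG almost entirely released at equilibrium.
system,ta_pct,chdg_pct,rho_matrix,q_w,nu2eq_ref,cp_ref,delta_c_ref,dc_ref
Collagen,0,0,1.195,6.80,0.136,953,2.5,58
Collagen-TA(5%),5,0,1.245,5.66,0.164,1150,3.7,103
Collagen-TA(10%),10,0,1.290,4.30,0.217,1521,6.4,261
Collagen-TA(15%),15,0,1.316,4.11,0.227,1591,7.0,306
Collagen-TA(5%)-CHDG(9.09%),5,9.09,1.248,4.06,0.230,1612,7.2,321
Collagen-TA(10%)-CHDG(9.09%),10,9.09,1.285,4.02,0.233,1633,7.4,336
Collagen-TA(15%)-CHDG(9.09%),15,9.09,1.319,4.16,0.225,1577,6.9,297
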