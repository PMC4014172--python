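cell_line,quality,alpha,alpha_se,alpha0,alpha0_se,beta,beta_se,y_d,k,k_se,k_exp,k_exp_se,rbe37
CHO-K1,Co-60,0.246,0.023,0.238,0.024,0.0152,0.0023,2.34,30.4,9.3,30,,0.757
CHO-K1,6 MV,0.190,0.034,0.179,0.035,0.0218,0.0033,2.36,36.5,11.2,39.4,13.1,0.689
CHO-K1,Cs-137,0.255,0.029,0.239,0.032,0.0270,0.0036,2.90,40.6,12.3,,,0.855
CHO-K1,200 kVp,0.284,0.051,0.245,0.070,0.0425,0.0083,4.51,50.9,14.1,50.9,14.1,1.000
CHO-K1,100 kVp,0.456,0.082,0.378,0.135,0.0833,0.0179,4.70,71.3,22.7,,,1.522
H1299,Co-60,0.130,0.033,0.121,0.036,0.0176,0.0048,2.34,33.6,9.2,,,0.539
H1299,6 MV,0.137,0.036,0.121,0.038,0.0319,0.0041,2.36,45.3,10.8,37.9,13.7,0.659
H1299,Cs-137,0.113,0.074,0.085,0.083,0.0474,0.0103,2.90,55.2,14.2,,,0.713
H1299,200 kVp,0.277,0.048,0.231,0.066,0.0526,0.0078,4.51,58.1,12.5,58.1,12.5,1.000
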