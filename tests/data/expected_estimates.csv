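param,estimate,se
beta_11,-4.340,0.521
beta_12,-8.705,1.440
beta_13,-12.851,2.246
beta_14,-17.020,3.142
beta_21,-2.781,0.343
beta_22,-6.514,1.026
beta_23,-10.768,1.777
beta_24,-14.717,2.689
beta_31,-3.738,0.416
beta_32,-6.293,1.147
beta_33,-9.868,2.002
beta_34,-14.733,3.210
beta_41,-3.905,0.396
beta_42,-7.433,1.079
beta_43,-10.997,1.774
beta_44,-15.083,2.589
beta_51,-3.544,0.315
beta_52,-6.030,0.818
beta_53,-9.198,1.385
beta_54,-15.030,2.833
delta_11,3.107,0.284
delta_12,3.125,0.369
delta_13,2.968,0.488
delta_14,2.984,0.651
delta_21,2.136,0.165
delta_22,2.868,0.188
delta_23,3.267,0.359
delta_24,3.033,0.496
delta_31,3.383,0.374
delta_32,2.312,0.384
delta_33,3.236,0.604
delta_34,4.403,1.601
delta_41,3.083,0.302
delta_42,2.785,0.283
delta_43,2.813,0.416
delta_44,3.226,0.528
delta_51,3.418,0.362
delta_52,2.397,0.330
delta_53,3.055,0.704
delta_54,5.625,1.870
omega_11,3.107,0.284
omega_12,3.116,0.210
omega_13,3.067,0.182
omega_14,3.046,0.192
omega_21,2.136,0.165
omega_22,2.502,0.106
omega_23,2.757,0.135
omega_24,2.826,0.131
omega_31,3.383,0.374
omega_32,2.847,0.177
omega_33,2.977,0.220
omega_34,3.333,0.386
omega_41,3.083,0.302
omega_42,2.934,0.168
omega_43,2.894,0.162
omega_44,2.977,0.162
omega_51,3.418,0.362
omega_52,2.907,0.187
omega_53,2.957,0.241
omega_54,3.624,0.451
alpha_1,1.397,0.259
alpha_2,1.302,0.228
alpha_3,1.105,0.215
alpha_4,1.267,0.217
alpha_5,1.037,0.169
kappa_3,-0.251,0.020
kappa_4,0.046,0.011
kappa_5,-0.006,0.003
lambda_6,0.001,0.000
eps_11,-0.110,0.019
eps_12,0.005,0.002
eps_21,-0.074,0.005
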