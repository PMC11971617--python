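pattern,eap,var
"(0,0,0,0,0)",0.000,1.000
"(1,0,0,0,0)",1.172,0.692
"(2,0,0,0,0)",1.968,0.459
"(3,0,0,0,0)",2.482,0.287
"(0,1,0,0,0)",1.106,0.710
"(1,1,0,0,0)",1.924,0.473
"(0,2,0,0,0)",1.878,0.487
"(1,2,0,0,0)",2.426,0.307
"(3,2,0,0,0)",2.945,0.091
"(0,3,0,0,0)",2.396,0.318
"(0,0,1,0,0)",0.962,0.750
"(1,0,1,0,0)",1.828,0.502
"(0,1,1,0,0)",1.779,0.517
"(1,1,1,0,0)",2.363,0.329
"(0,2,1,0,0)",2.332,0.340
"(1,0,2,0,0)",2.296,0.352
"(0,1,2,0,0)",2.262,0.364
"(0,2,2,0,0)",2.642,0.227
"(1,2,3,0,0)",2.986,0.068
"(0,1,4,0,0)",2.814,0.155
"(0,0,0,1,0)",1.080,0.717
"(0,1,0,1,0)",1.861,0.492
"(1,1,0,1,0)",2.415,0.311
"(0,2,0,1,0)",2.385,0.322
"(0,0,1,1,0)",1.761,0.522
"(0,1,1,1,0)",2.320,0.344
"(0,1,2,1,0)",2.634,0.230
"(0,0,0,2,0)",1.844,0.497
"(0,1,0,2,0)",2.374,0.326
"(0,2,0,2,0)",2.711,0.199
"(1,2,0,2,0)",2.919,0.105
"(2,2,0,2,0)",3.020,0.045
"(1,3,0,2,0)",3.016,0.048
"(0,1,1,2,0)",2.670,0.216
"(1,2,1,2,0)",3.006,0.055
"(1,3,2,2,0)",3.063,0.005
"(0,1,0,3,0)",2.704,0.202
"(0,1,1,3,0)",2.882,0.124
"(2,4,1,4,0)",3.149,0.065
"(0,0,0,0,1)",0.910,0.764
"(0,1,0,0,1)",1.744,0.527
"(1,1,0,0,1)",2.341,0.337
"(0,2,0,0,1)",2.308,0.348
"(1,2,0,0,1)",2.691,0.208
"(0,1,1,0,1)",2.237,0.372
"(0,1,2,0,1)",2.579,0.251
"(0,0,0,1,1)",1.725,0.533
"(1,1,0,1,1)",2.683,0.211
"(2,1,0,1,1)",2.905,0.112
"(2,2,3,1,1)",3.067,0.004
"(0,0,0,2,1)",2.284,0.356
"(1,1,0,2,1)",2.889,0.120
"(4,2,0,2,1)",3.071,0.009
"(0,0,1,2,1)",2.610,0.239
"(3,2,2,2,1)",3.083,0.021
"(0,0,0,3,1)",2.647,0.225
"(0,1,0,3,1)",2.873,0.128
"(1,4,3,3,1)",3.193,0.088
"(0,4,0,4,1)",3.068,0.005
"(0,4,2,4,1)",3.113,0.044
"(0,0,0,0,2)",1.599,0.570
"(2,2,0,0,2)",2.996,0.061
"(0,3,0,0,2)",2.852,0.138
"(0,1,1,0,2)",2.562,0.258
"(0,2,1,0,2)",2.824,0.151
"(3,4,2,0,2)",3.121,0.049
"(4,3,3,0,2)",3.205,0.093
"(0,1,0,1,2)",2.602,0.243
"(0,1,1,1,2)",2.818,0.153
"(2,2,1,1,2)",3.062,0.006
"(3,3,3,1,2)",3.193,0.088
"(0,0,0,2,2)",2.593,0.246
"(0,1,0,2,2)",2.842,0.143
"(0,2,0,2,2)",2.979,0.072
"(0,2,1,2,2)",3.035,0.033
"(0,3,3,3,2)",3.097,0.033
"(0,2,1,4,2)",3.066,0.003
"(1,4,1,4,2)",3.202,0.092
"(2,2,2,4,2)",3.193,0.088
"(0,0,0,0,3)",2.106,0.415
"(3,1,0,3,3)",3.080,0.018
"(1,0,0,4,3)",3.060,0.009
"(1,3,3,3,4)",3.434,0.186
"(2,4,4,3,4)",4.782,0.573
"(2,3,4,4,4)",4.762,0.568
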