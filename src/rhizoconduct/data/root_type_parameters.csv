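parameter,type,P0_mean,P0_sd,P1_mean,P1_sd,P2_mean,P2_sd,P3_mean,P3_sd,general_mean,general_sd
a,primary,0.054,0.012,0.064,0.017,0.067,0.01,0.091,0.01,0.069,0.003
a,seminal,0.052,0.011,0.062,0.016,0.066,0.01,0.081,0.011,0.065,0.003
a,crown,0.061,0.016,0.059,0.02,0.066,0.014,0.066,0.003,0.063,0.007
a,l-lateral,0.025,0.011,0.024,0.009,0.025,0.008,0.03,0.007,0.026,0.002
a,s-lateral,0.025,0.007,0.028,0.01,0.025,0.008,0.04,0.012,0.030,0.002
l_b,primary,0.8,0.899,1.879,2.385,3.183,2.236,3.777,5.681,2.410,2.033
l_b,seminal,2.55,2.333,3.883,2.432,3.969,4.574,1.642,0.814,3.011,1.546
l_b,crown,3.161,2.454,7.216,7.564,3.473,2.487,3.924,3.025,4.444,2.468
l_b,l-lateral,2.27,2.433,1.732,1.441,2.854,2.349,1.779,1.392,2.159,0.564
l_delay,primary,0.212,0.153,0.481,0.597,2.63,0.284,1.743,1.331,1.267,0.527
l_delay,seminal,0.499,0.364,0.941,0.784,1.038,0.864,0.94,0.535,0.855,0.230
l_delay,crown,0.194,0.124,0.666,0.625,0.547,0.476,0.666,0.428,0.518,0.210
l_delay,l-lateral,0.327,0.294,0.618,0.444,0.341,0.305,0.442,0.309,0.432,0.071
r,primary,3.951,0.766,3.35,1.252,4.417,0.865,4.627,0.486,4.086,0.317
r,seminal,3.28,1.955,2.149,1.417,2.912,0.644,3.239,1.698,2.895,0.567
r,crown,2.981,2.693,2.556,2.902,2.29,2.146,4.886,2.583,3.178,0.319
r,l-lateral,2.951,1.492,1.763,0.693,2.15,0.56,1.742,0.582,2.152,0.444
r,s-lateral,2.555,2.479,5.078,4.814,5.292,4.982,5.97,5.168,4.724,1.263
l_max,l-lateral,5.549,3.821,4.756,2.513,6.736,3.546,4.794,2.392,5.459,0.721
l_max,s-lateral,1.631,1.596,1.341,1.15,0.84,0.452,1.238,1.123,1.263,0.472
theta,l-lateral,1.194,0.375,1.262,0.309,1.344,0.324,1.413,0.324,1.303,0.029
theta,s-lateral,1.194,0.375,1.37,0.346,1.396,0.327,1.413,0.324,1.343,0.023
l_n,primary,0.466,0.045,0.457,0.085,0.536,0.122,0.545,0.187,0.501,0.060
l_n,seminal,0.847,0.327,0.519,0.116,0.767,0.202,0.773,0.234,0.727,0.087
l_n,crown,0.847,0.327,0.628,0.244,0.811,0.419,0.754,0.124,0.760,0.125
l_n,l-lateral,0.833,0.946,0.459,0.284,0.53,0.417,0.48,0.319,0.576,0.308
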