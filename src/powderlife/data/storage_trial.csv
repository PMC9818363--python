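treatment,condition,day,moisture_pct_wb,moisture_pct_wb_sd,aw,aw_sd,caking_pct,caking_pct_sd,carr_index_pct,carr_index_pct_sd,hygroscopicity,hygroscopicity_sd,prt_min,prt_min_sd,rr,rr_sd,L,L_sd,a,a_sd,b,b_sd,tpc_cfu_per_g,tpc_cfu_per_g_sd
control,ambient,0,5.613,0.03,0.28,0.03,10.191,1.03,22.356,2.03,23.041,2.02,1.423,0.13,6.047,0.13,57.337,3.13,5.463,1.06,27.128,2.03,661,1210
control,ambient,30,5.813,0.01,0.342,0.02,10.889,1.03,23.461,2.07,23.253,2.03,1.48,0.22,5.447,0.22,57.304,3.21,5.964,1.05,26.778,2.17,3721,1220
control,ambient,60,6.29,0.03,0.422,0.05,12.298,1.01,26.232,2.03,23.577,2.13,1.527,0.44,5.413,0.17,56.902,3.22,6.412,1.04,26.023,2.03,3872,1240
control,ambient,90,6.487,0.03,0.47,0.03,13.232,1.04,27.898,2.05,24.053,2.03,1.573,0.56,5.371,0.03,55.346,3.32,7.017,1.01,25.505,2.03,4299,1530
control,ambient,120,7.3,0.01,0.542,0.06,15.289,1.07,29.231,2.03,25.223,2.16,2.017,0.12,5.31,0.1,53.779,3.43,7.323,1.1,24.862,2.22,4663,1270
control,ambient,140,8.421,0.02,0.57,0.03,16.786,1.03,30.996,2.01,26.232,2.03,2.123,0.03,5.211,0.03,52.121,3.21,7.816,1.22,23.88,2.03,4987,1530
control,ambient,160,8.902,0.04,0.601,0.07,18.894,1.07,32.414,2.03,27.109,2.22,2.2,0.17,4.553,0.2,51.223,3.11,8.012,1.21,22.775,2.027,5239,1290
control,ambient,180,9.987,0.03,0.71,0.01,20.597,1.03,34.262,2.02,28.432,2.03,2.23,0.22,4.247,0.02,50.278,3.1,8.429,1.21,21.87,2.03,5601,1530
TCP,ambient,0,5.613,0.03,0.28,0.02,10.191,1.04,22.356,2.05,23.041,2.03,1.423,0.02,6.047,0.25,57.337,3.24,5.463,1.09,27.128,2.23,661,1210
TCP,ambient,30,5.71,0.05,0.322,0.07,10.226,1.03,23.476,2.03,23.173,2.22,1.463,0.14,5.481,0.03,57.327,3.03,5.896,1.03,27.074,2.43,3712,1550
TCP,ambient,60,5.743,0.04,0.413,0.03,10.27,1.03,25.651,2.03,23.321,2.03,1.503,0.13,5.483,0.29,57.267,3.1,6.357,1.18,26.871,2.21,3753,1210
TCP,ambient,90,5.826,0.01,0.452,0.01,10.383,1.04,26.204,2.02,23.867,2.11,1.54,0.02,5.453,0.28,56.967,3.03,7.007,1.23,26.271,2.43,3824,1530
TCP,ambient,120,5.891,0.03,0.505,0.03,10.805,1.07,27.329,2.03,24.073,2.03,1.87,0.05,5.393,0.03,55.428,3.19,7.223,1.22,25.762,2.12,3893,1210
TCP,ambient,140,5.936,0.02,0.533,0.04,11.353,1.08,29.662,2.07,24.784,2.03,2.04,0.04,4.557,0.07,54.873,3.11,7.547,1.21,25.176,2.25,3932,1530
TCP,ambient,160,6.033,0.02,0.574,0.03,12.033,1.03,31.221,2.03,25.439,2.36,2.097,0.13,4.752,0.3,54.247,3.18,7.943,1.32,24.842,2.21,4032,1230
TCP,ambient,180,6.113,0.03,0.601,0.02,12.363,1.07,32.654,2.09,26.023,2.03,2.12,0.23,4.843,0.13,53.993,3.11,8.023,1.32,24.017,2.23,4110,1190
SiO2,ambient,0,5.613,0.03,0.28,0.02,10.191,1.13,22.356,2.01,23.041,2.023,1.423,0.02,6.047,0.21,57.337,3.23,5.463,1.09,27.128,2.11,661,1270
SiO2,ambient,30,5.74,0.02,0.35,0.04,10.131,1.23,23.878,2.03,23.192,2.13,1.467,0.03,5.474,0.23,57.323,3.22,5.946,1.08,26.982,2.03,3744,1530
SiO2,ambient,60,5.753,0.03,0.411,0.03,10.456,1.07,25.904,2.02,23.371,2.03,1.503,0.11,5.457,0.27,57.215,3.21,6.28,1.07,26.772,2.11,3753,1530
SiO2,ambient,90,5.836,0.04,0.462,0.05,10.693,1.07,26.408,2.03,24.027,2.33,1.54,0.23,5.376,0.29,56.933,3.08,6.94,1.06,26.135,2.03,3824,1110
SiO2,ambient,120,5.99,0.03,0.522,0.03,11.152,1.06,27.442,2.01,24.671,2.03,2.026,0.07,5.288,0.11,55.348,3.19,7.047,1.03,25.552,2.03,3910,1530
SiO2,ambient,140,5.953,0.02,0.593,0.01,11.646,1.09,29.705,2.03,25.107,2.22,2.057,0.22,5.235,0.09,54.677,3.18,7.357,1.05,25.107,2.21,3950,1260
SiO2,ambient,160,6.05,0.03,0.621,0.03,12.233,1.04,32.217,2.05,25.957,2.17,2.103,0.44,4.812,0.12,54.071,3.16,7.862,1.03,24.336,2.23,4050,1290
SiO2,ambient,180,6.173,0.01,0.634,0.02,13.036,1.03,33.709,2.08,26.223,2.23,2.177,0.21,4.671,0.08,53.285,3.17,8.123,1.01,23.885,2.23,4174,1180
control,accelerated,0,5.613,0.03,0.28,0.03,10.191,1.09,22.356,2.13,23.041,2.01,1.423,0.05,6.047,0.17,57.337,3.21,5.463,1.09,27.128,2.11,661,1210
control,accelerated,30,6.567,0.02,0.411,0.07,11.237,1.03,24.521,2.23,23.767,2.03,1.453,0.23,5.417,0.03,56.323,3.03,6.019,1.03,26.878,2.16,4022,1240
control,accelerated,60,8.028,0.03,0.482,0.03,13.561,1.05,28.467,2.03,24.656,2.09,2.02,0.14,5.127,0.12,54.102,3.34,6.673,1.08,25.343,2.03,4661,1530
control,accelerated,90,8.997,0.04,0.648,0.05,15.489,1.03,29.219,2.33,25.062,2.03,2.113,0.03,5.033,0.03,52.217,3.03,7.227,1.03,24.223,2.23,5128,1270
control,accelerated,120,9.58,0.05,0.692,0.03,17.409,1.03,31.515,2.04,26.137,2.09,2.16,0.16,4.971,0.03,50.789,3.33,7.661,1.08,23.616,2.03,5780,1530
control,accelerated,140,10.93,0.06,0.742,0.02,19.843,1.01,32.757,2.09,28.232,2.03,2.26,0.18,4.541,0.18,48.668,3.22,8.232,1.03,21.443,2.23,6216,1280
control,accelerated,160,11.002,0.03,0.807,0.03,21.353,1.01,34.227,2.03,29.553,2.11,2.37,0.14,4.053,0.12,46.243,3.22,8.767,1.04,19.998,2.03,6908,1280
control,accelerated,180,11.99,0.01,0.881,0.03,24.761,1.08,36.981,2.31,31.247,2.43,2.583,0.13,3.653,0.08,45.561,3.11,9.251,1.06,18.233,2.21,7980,1570
TCP,accelerated,0,5.613,0.03,0.28,0.04,10.191,1.03,22.356,2.11,23.041,2.23,1.423,0.04,6.047,0.18,57.337,3.02,5.463,1.07,27.128,2.33,661,1280
TCP,accelerated,30,5.862,0.06,0.384,0.03,10.646,1.06,24.246,2.04,23.471,2.33,1.437,0.06,5.463,0.16,56.383,3.23,5.641,1.03,27.471,2.03,3852,1530
TCP,accelerated,60,5.94,0.03,0.454,0.03,11.056,1.06,27.451,2.03,24.021,2.05,1.55,0.11,5.351,0.26,55.615,3.21,6.853,1.09,26.022,2.21,3934,1260
TCP,accelerated,90,6.136,0.03,0.505,0.02,11.926,1.03,28.206,2.06,24.773,2.06,2.013,0.03,5.181,0.27,54.867,3.32,7.287,1.03,25.773,2.03,4147,1530
TCP,accelerated,120,6.276,0.01,0.553,0.03,12.583,1.01,29.509,2.03,25.247,2.16,2.047,0.15,4.991,0.31,53.803,3.34,7.627,1.09,24.241,2.21,4268,1270
TCP,accelerated,140,6.632,0.03,0.621,0.02,13.246,1.03,31.748,2.08,26.477,2.03,2.147,0.03,4.463,0.21,53.293,3.45,8.037,1.03,23.265,2.03,4694,1530
TCP,accelerated,160,6.853,0.04,0.642,0.03,13.953,1.02,33.216,2.24,27.666,2.04,2.223,0.19,4.223,0.29,52.647,3.27,8.343,1.07,22.343,2.31,5252,1290
TCP,accelerated,180,7.273,0.02,0.72,0.04,14.803,1.03,34.47,2.25,28.289,2.17,2.32,0.18,3.863,0.06,51.653,3.29,8.853,1.04,21.271,2.03,6051,1330
SiO2,accelerated,0,5.613,0.02,0.28,0.08,10.191,1.05,22.356,2.08,23.041,2.5,1.423,0.21,6.047,0.11,57.337,3.1,5.463,1.05,27.128,2.11,661,1530
SiO2,accelerated,30,5.846,0.03,0.382,0.07,10.746,1.03,24.601,2.01,23.527,2.03,1.448,0.27,5.453,0.03,56.33,3.23,5.743,1.03,27.667,2.03,3842,1100
SiO2,accelerated,60,6.21,0.01,0.464,0.03,11.146,1.07,27.808,2.03,24.132,2.3,1.56,0.21,5.421,0.16,55.53,3.12,6.757,1.06,26.017,2.22,3944,1530
SiO2,accelerated,90,6.616,0.03,0.515,0.03,12.053,1.03,28.461,2.02,25.073,2.03,2.037,0.27,5.295,0.03,54.946,3.26,7.296,1.03,25.175,2.34,4610,1530
SiO2,accelerated,120,6.77,0.04,0.566,0.02,12.953,1.04,30.221,2.03,26.023,2.2,2.06,0.36,5.021,0.16,53.68,3.23,7.583,1.03,24.112,2.03,4770,1100
SiO2,accelerated,140,6.896,0.03,0.613,0.03,13.464,1.04,32.336,2.05,27.067,2.03,2.18,0.55,4.722,0.03,53.246,3.54,8.057,1.04,23.136,2.03,4894,1190
SiO2,accelerated,160,7.073,0.05,0.654,0.03,14.056,1.02,34.016,2.03,28.223,2.44,2.27,0.44,4.242,0.11,52.543,3.04,8.372,1.03,22.237,2.21,5073,1530
SiO2,accelerated,180,7.43,0.03,0.731,0.04,15.242,1.03,35.007,2.23,29.027,2.22,2.363,0.28,3.763,0.01,50.821,3.23,8.712,1.04,21.116,2.29,6242,1100
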