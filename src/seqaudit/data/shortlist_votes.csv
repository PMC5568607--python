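transformation,id,true_label,mG,CS,GB,VN,Ph,Od,Ta
aac,a8dz71_danre,mG,0.045,0.035,0.000,0.205,0.370,0.330,0.015
aac,a8dz72_danre,mG,0.028,0.045,0.006,0.198,0.435,0.209,0.079
aac,q5i5d4_9tele,mG,0.055,0.011,0.022,0.088,0.203,0.599,0.022
aac,q5i5c3_9tele,mG,0.032,0.005,0.000,0.074,0.159,0.725,0.005
aac,XP_002735016,mG,0.026,0.000,0.958,0.000,0.016,0.000,0.000
aac,XP_002738008,GB,0.784,0.011,0.086,0.011,0.086,0.000,0.022
aac,a7sdg9_nemve,Ph,0.836,0.011,0.063,0.005,0.058,0.011,0.016
aac,b3s157_triad,Ph,0.670,0.017,0.067,0.095,0.095,0.034,0.022
aac,b3s609_triad,Ph,0.455,0.037,0.175,0.048,0.101,0.016,0.169
aac,XP_002731604,Ph,0.519,0.021,0.270,0.026,0.111,0.016,0.037
aac,XP_002732067,Ph,0.613,0.058,0.145,0.029,0.116,0.023,0.017
aac,XP_001521044,Ph,0.401,0.006,0.271,0.051,0.141,0.023,0.107
aac,q9pwe1_ictpu,Ph,0.825,0.005,0.057,0.010,0.103,0.000,0.000
aac,b0uyj3_danre,Ph,0.877,0.000,0.005,0.000,0.118,0.000,0.000
aac,XP_001075542,Ph,0.000,0.006,0.000,0.161,0.122,0.706,0.006
aac,XP_001521075,Ph,0.549,0.006,0.429,0.000,0.017,0.000,0.000
sez,a8dz71_danre,mG,0.016,0.011,0.000,0.216,0.465,0.270,0.022
sez,a8dz72_danre,mG,0.103,0.034,0.011,0.069,0.497,0.194,0.091
sez,q5i5d4_9tele,mG,0.034,0.028,0.000,0.101,0.235,0.598,0.006
sez,q5i5c3_9tele,mG,0.033,0.022,0.011,0.116,0.254,0.547,0.017
sez,XP_002163014,mG,0.119,0.017,0.028,0.435,0.294,0.079,0.028
sez,b3rj55_triad,GB,0.466,0.052,0.110,0.084,0.194,0.010,0.084
sez,XP_002738008,GB,0.574,0.024,0.136,0.077,0.118,0.012,0.059
sez,a7sdg9_nemve,Ph,0.615,0.046,0.126,0.057,0.126,0.006,0.023
sez,a7s0d2_nemve,Ph,0.591,0.069,0.103,0.039,0.128,0.034,0.034
sez,b3s157_triad,Ph,0.706,0.011,0.068,0.056,0.079,0.000,0.079
sez,q4spr3_tetng,Ph,0.280,0.065,0.480,0.010,0.120,0.005,0.040
sez,NP_001093020,Ph,0.022,0.005,0.102,0.699,0.140,0.027,0.005
sez,b0uyj3_danre,Ph,0.870,0.005,0.041,0.010,0.073,0.000,0.000
sez,XP_001075542,Ph,0.030,0.015,0.005,0.197,0.099,0.611,0.044
sez,XP_001521075,Ph,0.430,0.006,0.436,0.017,0.087,0.000,0.023
dav,a8dz71_danre,mG,0.022,0.043,0.016,0.239,0.342,0.299,0.038
dav,a8dz72_danre,mG,0.006,0.017,0.000,0.115,0.293,0.557,0.011
dav,q5i5c3_9tele,mG,0.124,0.006,0.006,0.102,0.085,0.667,0.011
dav,a7s0d3_nemve,mG,0.108,0.072,0.006,0.174,0.419,0.186,0.036
dav,b3s5y8_triad,mG,0.059,0.000,0.909,0.016,0.005,0.000,0.011
dav,XP_002187232,mG,0.117,0.000,0.766,0.006,0.070,0.006,0.035
dav,a7s6r9_nemve,GB,0.683,0.032,0.063,0.069,0.111,0.005,0.037
dav,b3rj55_triad,GB,0.559,0.028,0.107,0.085,0.153,0.006,0.062
dav,XP_002738008,GB,0.560,0.010,0.015,0.210,0.120,0.055,0.030
dav,a8q0q5_bruma,GB,0.566,0.032,0.111,0.127,0.116,0.011,0.037
dav,a7sdg9_nemve,Ph,0.564,0.069,0.112,0.106,0.117,0.005,0.027
dav,a7s1x6_nemve,Ph,0.697,0.022,0.059,0.059,0.119,0.005,0.038
dav,a7s0d2_nemve,Ph,0.556,0.012,0.175,0.058,0.135,0.053,0.012
dav,b3s157_triad,Ph,0.674,0.032,0.128,0.021,0.080,0.000,0.064
dav,XP_002940870,Ph,0.269,0.183,0.059,0.274,0.118,0.016,0.081
dav,XP_002941708,Ph,0.589,0.044,0.039,0.100,0.139,0.000,0.089
dav,NP_001093018,Ph,0.000,0.000,0.000,0.906,0.094,0.000,0.000
dav,NP_001093016,Ph,0.010,0.000,0.000,0.907,0.074,0.005,0.005
dav,NP_001093017,Ph,0.006,0.039,0.011,0.782,0.134,0.006,0.022
dav,XP_002936172,Ph,0.000,0.000,0.000,0.895,0.074,0.032,0.000
dav,XP_684341,Ph,0.517,0.095,0.060,0.109,0.090,0.015,0.114
dav,q9pwe1_ictpu,Ph,0.923,0.000,0.000,0.012,0.053,0.000,0.012
dav,XP_001075542,Ph,0.027,0.000,0.000,0.212,0.125,0.625,0.011
dav,XP_001521075,Ph,0.305,0.021,0.574,0.005,0.068,0.016,0.011
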