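no,structure,wt_expo_pct,wt_stat_pct,ldt_go1_pct,ldt_go2_pct,rt_min,rt_sd,theoretical_mass,delta_ppm
1,gm-AEJ_NH2,36.519,41.440,48.001,34.926,5.32,0.05,869.3867,4.01
2,gm-AE,4.239,10.518,9.628,6.887,6.79,0.03,698.2859,2.77
3,gm-AEJA,22.572,3.270,4.019,28.131,6.80,0.01,941.4078,3.38
4,gm-AE (Anh),0.880,1.158,0.656,0.505,11.06,0.00,678.2597,1.52
5,gm-AEJ_NH2 (Anh),0.522,0.682,0.472,0.161,8.61,0.01,849.3605,2.29
6,gm-AEJ_NH2A,0.254,0.290,0.343,0.012,6.37,0.27,940.4238,1.39
7,gm-AEJ,0.711,0.356,0.193,0.014,5.66,0.04,870.3707,2.14
8,gm-AEJAG,0.494,0.064,0.130,0.247,6.49,0.02,998.4293,1.46
9,gm-AF,0.072,0.171,0.096,,14.54,0.01,716.3117,0.89
10,gm-AEJAA,0.353,0.074,0.094,0.067,8.08,0.39,1012.4450,2.97
11,gm-A,0.335,1.385,0.534,0.024,6.26,0.03,569.2433,1.8
12,gm-AEJA (Anh),0.425,0.093,0.079,0.131,10.42,0.01,921.3816,1.45
13,gm-AEJAK,0.114,0.021,0.042,0.057,5.86,0.03,1069.5028,1.07
14,gm-AY,0.032,0.100,0.042,,10.72,0.01,732.3066,0.52
15,gm-AI,0.027,0.070,0.038,,12.89,0.00,682.3274,0.81
16,gm-AI (Anh),,0.029,,,12.75,,662.3012,0.99
17,gm-AEJAR,0.121,0.028,0.037,0.062,6.42,0.03,1097.5089,1.57
18,gm-AEJAH,0.100,0.035,0.035,0.050,5.99,0.03,1078.4667,1.41
19,gm-AEJAN,0.022,0.069,0.033,0.038,10.37,4.33,1055.4508,1.72
20,gm-AI (-Ac),0.055,,,,6.29,,640.3169,0.24
21,gm-AEJ_NH2 (-Ac),0.036,0.015,0.023,0.022,5.05,0.06,827.3762,1.15
22,gm-AQ,0.057,0.026,0.022,0.047,5.77,0.04,697.3019,0.97
23,gm-AEJAE,0.029,0.019,0.018,0.031,7.29,0.01,1070.4504,0.50
24,gm-AEJ (Anh),0.011,,0.017,,9.03,0.00,850.3445,1.15
25,gm-AEJA (-Ac),0.021,0.002,0.007,0.027,6.43,0.02,899.3973,1.11
26,gm-AEJ_NH2A (Anh),,,0.006,,9.93,,920.3976,1.17
27,gm-AE (-Ac),,0.030,0.003,,5.62,0.01,656.2754,0.14
28,gm-AF (-Ac),,,0.003,,16.28,,674.3012,1.24
29,gm-AEJ_NH2=gm-AEJA,13.782,15.265,18.938,15.714,8.43,0.00,1792.7836,3.35
30,gm-AEJ_NH2=gm-A,2.592,13.391,7.317,0.037,8.60,0.00,1420.6194,1.75
31,gm-AEJ_NH2=gm-AEJA (Anh),3.741,4.098,4.220,4.109,10.87,0.00,1772.7574,2.38
32,gm-AEJA=gm-AEJA,6.802,2.822,2.318,6.976,9.59,0.00,1864.8047,2.51
33,gm-AEJ_NH2=gm-A (Anh),0.243,0.794,0.609,,11.43,0.01,1400.5932,0.85
34,gm-AEJA=gm-A,2.520,2.028,0.512,0.011,10.06,0.00,1492.6405,1.02
35,gm-AEJA=gm-AEJA (Anh),0.729,0.388,0.199,0.601,12.01,0.00,1844.7785,1.37
36,gm-AEJ=gm-AEJA,0.186,0.136,0.127,,9.03,0.05,1793.7676,0.68
37,gm-AEJA=gm-A (Anh),0.317,0.197,0.074,,12.87,0.02,1472.6143,0.41
38,gm-AEJAG=gm-AEJA,0.134,0.055,0.049,0.078,9.18,0.00,1921.8262,0.54
39,gm-AEJ=gm-AEJA (Anh),0.029,0.023,0.034,,11.46,0.02,1773.7414,1.45
40,gm-AEJAG=gm-A,0.068,0.030,0.022,0.013,10.42,1.48,1549.6617,3.24
41,gm-AEJ=gm-A,0.048,0.145,0.019,,9.38,0.00,1421.6034,0.94
42,gm-AEJA=gm-AEJA (Anh),,0.014,,,9.84,,1844.7786,0.09
43,gm-AEJAA=gm-AEJA,0.034,0.009,0.016,0.023,9.84,0.01,1935.8419,0.67
44,gm-AEJ_NH2A=gm-AEJA,0.007,0.008,0.012,,9.32,0.04,1863.8207,0.70
45,gm-AEJAG=gm-AEJA (Anh),0.032,0.014,0.010,0.016,11.53,0.01,1901.8000,1.14
46,gm-AEJAR=gm-AEJA,0.017,,0.006,0.007,9.00,0.00,2020.9058,0.32
47,gm-AEJAN=gm-AEJA,,,0.005,0.004,8.76,0.01,1978.8477,0.81
48,gm-AEJ_NH2A=gm-AEJA (Anh),,,0.004,,11.56,,1843.7945,0.37
49,gm-AEJ_NH2=gm-AEJA (-Ac),0.005,,0.003,0.004,8.18,0.03,1750.7731,2.03
50,gm-AEJAH=gm-AEJA,0.013,,,0.006,8.64,0.00,2001.8636,0.74
51,gm-AEJ_NH2A=gm-A,,,0.005,,16.44,,1491.6565,0.55
52,gm-AEJAA=gm-AEJA (Anh),0.006,,0.002,0.004,12.12,0.01,1915.8157,0.63
53,gm-AEJAG=gm-A (Anh),0.005,,0.002,,9.71,2.72,1529.6355,1.74
54,gm-AEJAR=gm-AEJA (Anh),0.004,,,,11.24,,2000.8796,0.61
55,gm-AEJ_NH2=gm-AEJA=gm-AEJA,0.370,0.384,0.551,0.554,9.97,0.00,2716.1805,0.96
56,gm-AEJ_NH2=gm-AEJA=gm-AEJA (Anh),0.180,0.196,0.210,0.229,11.84,0.00,2696.1543,0.78
57,gm-AEJA=gm-AEJA=gm-AEJA,0.099,0.045,0.119,0.136,10.84,0.00,2788.2016,1.89
58,gm-AEJA=gm-AEJA=gm-AEJA (Anh),0.032,0.015,0.024,0.033,12.67,0.03,2768.1754,0.28
59,gm-AEJ=gm-AEJA=gm-AEJA,,,0.019,,10.59,0.00,2717.1645,1.18
60,gm-AEJ=gm-AEJA=gm-AEJA (Anh),,,0.005,,12.51,,2697.1383,0.52
61,gm-AEJAG=gm-AEJA=gm-AEJA,0.005,,0.004,0.003,10.49,0.01,2845.2231,0.53
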