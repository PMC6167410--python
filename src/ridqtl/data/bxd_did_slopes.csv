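strain,slope_2h,intercept_2h,se_2h,slope_4h,intercept_4h,se_4h
BXD40,0.329,1.54,0.07,0.541,3.05,0.54
BXD24,0.297,1.51,0.07,0.545,3.20,0.55
C57BL/6J,0.278,3.20,0.11,-0.077,6.60,-0.08
BXD49,0.246,2.48,0.03,-0.455,6.01,-0.46
BXD34,0.238,1.16,0.04,0.408,2.46,0.41
BXD68,0.218,2.09,0.07,-0.002,4.96,0.00
BXD50,0.211,1.18,0.01,0.232,2.83,0.23
BXD77,0.199,1.22,0.02,0.374,2.47,0.37
BXD83,0.197,1.50,0.03,0.408,3.02,0.41
BXD62,0.183,1.57,0.03,0.153,3.59,0.15
BXD90,0.169,1.93,0.03,0.188,4.05,0.19
BXD73a,0.168,1.95,0.01,0.362,3.80,0.36
BXD75,0.166,1.21,0.04,0.198,2.62,0.20
BXD100,0.161,1.57,0.04,0.139,3.54,0.14
BXD70,0.160,2.23,0.06,0.132,4.88,0.13
BXD98,0.150,4.28,0.30,-0.318,6.87,-0.32
BXD73b,0.146,1.58,0.01,0.319,3.04,0.32
BXD78,0.146,2.61,0.03,0.195,5.72,0.19
BXD71,0.144,1.91,0.03,0.272,4.37,0.27
BXD60,0.134,1.75,0.02,0.150,3.81,0.15
BXD65b,0.134,1.96,0.04,-0.109,4.42,-0.11
BXD48,0.134,2.76,0.02,0.542,5.02,0.54
BXD44,0.127,1.74,0.06,0.296,2.91,0.30
BXD101,0.125,2.19,0.06,0.355,3.85,0.35
BXD87,0.120,1.58,0.04,0.219,3.23,0.22
BXD73,0.118,1.94,0.04,0.060,4.28,0.06
BXD65,0.116,1.73,0.03,0.232,3.36,0.23
BXD61,0.109,1.21,0.08,-0.372,3.90,-0.37
BXD43,0.107,1.83,0.03,0.288,3.39,0.29
BXD102,0.103,1.14,0.19,0.183,1.84,0.18
BXD86,0.103,2.09,0.03,0.218,4.13,0.22
BXD69,0.101,2.03,0.03,0.197,3.58,0.20
BXD55,0.088,1.79,0.04,0.122,3.17,0.12
BXD51,0.080,2.36,0.03,0.379,4.08,0.38
BXD66,0.047,2.47,0.03,0.085,4.33,0.09
BXD32,0.018,1.61,0.01,0.075,2.73,0.07
BXD4S,0.007,2.56,0.21,-0.356,5.57,-0.36
BXD79,-0.017,2.61,0.03,-0.080,5.25,-0.08
BXD63,-0.026,2.25,0.05,-0.125,4.52,-0.13
DBA/2J,-0.041,2.17,0.09,-0.040,4.32,-0.04
BXD48a,-0.046,2.89,0.05,-0.264,5.72,-0.26
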