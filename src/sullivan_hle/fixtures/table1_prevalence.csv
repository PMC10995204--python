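age_start,age_width,sex,residence,division,condition,prevalence,n_sample
18,2,male,total,total,hypertension,0.106,
18,2,female,total,total,hypertension,0.050,
18,2,total,total,total,hypertension,0.068,
18,2,male,total,total,diabetes,0.057,
18,2,female,total,total,diabetes,0.029,
18,2,total,total,total,diabetes,0.038,
18,2,male,total,total,either,0.157,
18,2,female,total,total,either,0.078,
18,2,total,total,total,either,0.103,
18,2,male,total,total,both,0.000,
18,2,female,total,total,both,0.000,
18,2,total,total,total,both,0.000,
20,5,male,total,total,hypertension,0.128,
20,5,female,total,total,hypertension,0.076,
20,5,total,total,total,hypertension,0.095,
20,5,male,total,total,diabetes,0.051,
20,5,female,total,total,diabetes,0.037,
20,5,total,total,total,diabetes,0.042,
20,5,male,total,total,either,0.163,
20,5,female,total,total,either,0.114,
20,5,total,total,total,either,0.131,
20,5,male,total,total,both,0.018,
20,5,female,total,total,both,0.001,
20,5,total,total,total,both,0.006,
25,5,male,total,total,hypertension,0.115,
25,5,female,total,total,hypertension,0.140,
25,5,total,total,total,hypertension,0.130,
25,5,male,total,total,diabetes,0.036,
25,5,female,total,total,diabetes,0.056,
25,5,total,total,total,diabetes,0.049,
25,5,male,total,total,either,0.140,
25,5,female,total,total,either,0.183,
25,5,total,total,total,either,0.167,
25,5,male,total,total,both,0.007,
25,5,female,total,total,both,0.011,
25,5,total,total,total,both,0.010,
30,5,male,total,total,hypertension,0.168,
30,5,female,total,total,hypertension,0.213,
30,5,total,total,total,hypertension,0.195,
30,5,male,total,total,diabetes,0.069,
30,5,female,total,total,diabetes,0.080,
30,5,total,total,total,diabetes,0.076,
30,5,male,total,total,either,0.220,
30,5,female,total,total,either,0.257,
30,5,total,total,total,either,0.243,
30,5,male,total,total,both,0.011,
30,5,female,total,total,both,0.032,
30,5,total,total,total,both,0.024,
35,5,male,total,total,hypertension,0.221,
35,5,female,total,total,hypertension,0.314,
35,5,total,total,total,hypertension,0.270,
35,5,male,total,total,diabetes,0.088,
35,5,female,total,total,diabetes,0.116,
35,5,total,total,total,diabetes,0.103,
35,5,male,total,total,either,0.286,
35,5,female,total,total,either,0.384,
35,5,total,total,total,either,0.338,
35,5,male,total,total,both,0.031,
35,5,female,total,total,both,0.046,
35,5,total,total,total,both,0.039,
40,5,male,total,total,hypertension,0.220,
40,5,female,total,total,hypertension,0.373,
40,5,total,total,total,hypertension,0.303,
40,5,male,total,total,diabetes,0.137,
40,5,female,total,total,diabetes,0.125,
40,5,total,total,total,diabetes,0.130,
40,5,male,total,total,either,0.313,
40,5,female,total,total,either,0.441,
40,5,total,total,total,either,0.383,
40,5,male,total,total,both,0.052,
40,5,female,total,total,both,0.059,
40,5,total,total,total,both,0.056,
45,5,male,total,total,hypertension,0.283,
45,5,female,total,total,hypertension,0.434,
45,5,total,total,total,hypertension,0.369,
45,5,male,total,total,diabetes,0.117,
45,5,female,total,total,diabetes,0.152,
45,5,total,total,total,diabetes,0.136,
45,5,male,total,total,either,0.342,
45,5,female,total,total,either,0.497,
45,5,total,total,total,either,0.430,
45,5,male,total,total,both,0.060,
45,5,female,total,total,both,0.092,
45,5,total,total,total,both,0.078,
50,5,male,total,total,hypertension,0.349,
50,5,female,total,total,hypertension,0.475,
50,5,total,total,total,hypertension,0.408,
50,5,male,total,total,diabetes,0.179,
50,5,female,total,total,diabetes,0.173,
50,5,total,total,total,diabetes,0.176,
50,5,male,total,total,either,0.458,
50,5,female,total,total,either,0.542,
50,5,total,total,total,either,0.497,
50,5,male,total,total,both,0.070,
50,5,female,total,total,both,0.118,
50,5,total,total,total,both,0.093,
55,5,male,total,total,hypertension,0.376,
55,5,female,total,total,hypertension,0.510,
55,5,total,total,total,hypertension,0.450,
55,5,male,total,total,diabetes,0.140,
55,5,female,total,total,diabetes,0.168,
55,5,total,total,total,diabetes,0.156,
55,5,male,total,total,either,0.452,
55,5,female,total,total,either,0.552,
55,5,total,total,total,either,0.507,
55,5,male,total,total,both,0.073,
55,5,female,total,total,both,0.118,
55,5,total,total,total,both,0.098,
60,5,male,total,total,hypertension,0.436,
60,5,female,total,total,hypertension,0.540,
60,5,total,total,total,hypertension,0.486,
60,5,male,total,total,diabetes,0.183,
60,5,female,total,total,diabetes,0.152,
60,5,total,total,total,diabetes,0.170,
60,5,male,total,total,either,0.530,
60,5,female,total,total,either,0.602,
60,5,total,total,total,either,0.564,
60,5,male,total,total,both,0.093,
60,5,female,total,total,both,0.110,
60,5,total,total,total,both,0.101,
65,5,male,total,total,hypertension,0.483,
65,5,female,total,total,hypertension,0.550,
65,5,total,total,total,hypertension,0.512,
65,5,male,total,total,diabetes,0.164,
65,5,female,total,total,diabetes,0.133,
65,5,total,total,total,diabetes,0.150,
65,5,male,total,total,either,0.556,
65,5,female,total,total,either,0.599,
65,5,total,total,total,either,0.575,
65,5,male,total,total,both,0.113,
65,5,female,total,total,both,0.092,
65,5,total,total,total,both,0.104,
70,5,male,total,total,hypertension,0.510,
70,5,female,total,total,hypertension,0.527,
70,5,total,total,total,hypertension,0.517,
70,5,male,total,total,diabetes,0.193,
70,5,female,total,total,diabetes,0.155,
70,5,total,total,total,diabetes,0.178,
70,5,male,total,total,either,0.579,
70,5,female,total,total,either,0.584,
70,5,total,total,total,either,0.581,
70,5,male,total,total,both,0.120,
70,5,female,total,total,both,0.094,
70,5,total,total,total,both,0.109,
75,5,male,total,total,hypertension,0.448,
75,5,female,total,total,hypertension,0.627,
75,5,total,total,total,hypertension,0.526,
75,5,male,total,total,diabetes,0.129,
75,5,female,total,total,diabetes,0.148,
75,5,total,total,total,diabetes,0.138,
75,5,male,total,total,either,0.518,
75,5,female,total,total,either,0.672,
75,5,total,total,total,either,0.579,
75,5,male,total,total,both,0.071,
75,5,female,total,total,both,0.115,
75,5,total,total,total,both,0.090,
80,open,male,total,total,hypertension,0.573,
80,open,female,total,total,hypertension,0.688,
80,open,total,total,total,hypertension,0.635,
80,open,male,total,total,diabetes,0.153,
80,open,female,total,total,diabetes,0.114,
80,open,total,total,total,diabetes,0.133,
80,open,male,total,total,either,0.649,
80,open,female,total,total,either,0.736,
80,open,total,total,total,either,0.694,
80,open,male,total,total,both,0.090,
80,open,female,total,total,both,0.081,
80,open,total,total,total,both,0.085,
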