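name,r2_cal,rmse_cal,r2_cv,rmse_cv,rpd
acetaldehyde,0.220,0.160,0.120,0.170,1.37
2-methylfuran,0.313,0.092,0.249,0.097,1.13
3-methylbutanal,0.080,0.02,0.000,0.020,1.22
"2,3-butanedione",0.285,0.065,0.188,0.070,1.16
"2,3-pentanedione",0.384,0.057,0.299,0.061,1.31
hexanal,0.197,0.017,0.046,0.019,0.84
1-methyl-1H-pyrrole,0.331,0.098,0.164,0.108,1.57
pyridine,0.417,1.906,0.236,2.193,1.72
pyrazine,0.608,0.416,0.479,0.482,1.27
2-methyl-pyrazine,0.689,1.841,0.552,2.222,1.48
acetoin,0.367,0.049,0.257,0.054,1.09
acetol,0.427,0.346,0.319,0.379,1.27
"2,5-dimethylpyrazine",0.606,0.790,0.441,0.951,1.47
"2,6-dimethylpyrazine",0.646,0.843,0.512,0.992,1.43
ethylpyrazine,0.755,0.339,0.631,0.418,1.62
"2,3-dimethylpyrazine",0.378,0.235,0.229,0.263,1.08
1-hydroxy-2-butanone,0.484,0.028,0.378,0.031,1.34
3-ethylpyridine,0.362,0.040,0.160,0.046,1.85
2-ethyl-6-methylpyrazine,0.645,0.414,0.538,0.478,1.51
2-ethyl-5-methylpyrazine,0.666,0.259,0.534,0.308,1.46
2-ethyl-3-methylpyrazine,0.602,0.182,0.459,0.214,1.26
"2,3-diethylpyrazine",0.657,0.001,0.509,0.003,1.36
"3-ethyl-2,5-dimethylpyrazine",0.438,0.366,0.321,0.405,1.27
acetic acid,0.386,3.618,0.146,4.299,1.04
furfural,0.642,1.928,0.520,2.242,1.59
acetoxyacetone,0.630,0.081,0.542,0.091,1.53
furfurylmethyl sulphide,0.390,0.036,0.320,0.038,1.39
"2-ethyl-3,5-dimethylpyrazine",0.090,0.001,0.010,0.001,1.82
furaneol,0.572,0.085,0.481,0.094,1.38
2-acetylfuran,0.584,0.282,0.505,0.309,1.54
ethyl propanoate,0.651,0.074,0.580,0.082,1.54
2-furanmethanol acetate,0.565,0.262,0.518,0.276,1.74
propanoic acid,0.576,0.241,0.470,0.270,1.34
5-methylfurfural,0.690,1.038,0.578,1.226,1.67
"2,3-butanediol",0.120,0.020,0.040,0.020,0.91
2-formyl-1-methylpyrrole,0.180,0.120,0.090,0.120,1.29
γ-butyrolactone,0.200,0.080,0.100,0.090,1.13
2-furanmethanol,0.210,2.19,0.190,2.390,1.11
3-methyl-butanoic acid,0.284,0.257,0.210,0.271,1.16
N-acetyl-4(H)-pyridine,0.320,0.054,0.238,0.058,1.35
"3-hydroxy-4,5-dimethyl-2(5H)-furanone",0.598,0.053,0.529,0.057,1.43
3-methoxy-5-methyl-2-cyclopenten-1-one,0.362,0.015,0.255,0.017,1.07
3-methyl-2-butenoic acid,0.443,0.002,0.333,0.002,1.26
"3-methyl-1,2-cyclopentanedione",0.090,0.180,0.000,0.19,1.03
guaiacol,0.559,0.161,0.486,0.175,1.87
2-(1H-pyrrol-2-yl)-ethanone,0.501,0.130,0.441,0.138,1.34
2-formylpyrrole,0.446,0.213,0.352,0.231,1.30
phenol,0.273,0.225,0.307,0.237,1.70
4-ethylguaiacol,0.507,0.0005,0.434,0.0005,1.36
4-vinylguaiacol,0.483,0.118,0.423,0.126,1.25
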