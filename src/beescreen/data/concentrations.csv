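code,Pb,Cd,As,Hg,Cr,Fe,Co,Ni,Cu,Zn,Se
FS-01,0.128,<0.006,0.017,0.007,0.117,17.800,0.005,0.305,0.470,12.700,<0.015
FS-02,0.176,<0.006,0.029,<0.007,0.115,1.4700,0.005,0.745,0.136,1.870,<0.015
FS-03,0.057,<0.006,0.028,<0.007,0.091,1.460,0.003,0.117,0.362,2.630,<0.015
FS-04,0.074,<0.006,0.017,0.007,0.200,82.100,0.014,0.093,22.400,3.070,1.920
FS-05,0.162,0.010,0.015,0.012,0.077,1.300,0.006,0.141,15.200,2.270,<0.015
FS-06,0.161,<0.006,0.016,<0.007,0.258,11.100,0.005,0.119,4.930,22.100,0.047
FS-07,0.143,0.007,0.018,<0.007,0.193,9.230,0.004,0.102,2.290,13.200,0.026
FS-08,0.118,<0.006,0.018,<0.007,0.215,16.400,0.009,0.122,0.262,5.480,<0.015
FS-09,0.060,<0.006,0.020,<0.007,0.135,3.830,0.004,0.091,1.190,6.340,0.021
FS-10,0.096,0.007,0.015,<0.007,0.071,1.980,0.009,0.101,0.180,41.40,<0.015
FS-11,0.086,0.006,0.019,<0.007,0.118,1.480,0.007,0.052,0.146,0.8860,<0.015
FS-12,0.093,<0.006,0.015,<0.007,0.155,1005.000,0.014,0.070,0.085,2.190,<0.015
FS-13,0.049,<0.006,0.018,0.009,0.523,2.630,0.403,0.082,0.765,179.000,<0.015
FS-14,0.036,<0.006,0.022,<0.007,0.528,2.530,0.006,0.071,0.328,1.890,0.020
FS-15,0.067,0.023,0.036,<0.007,0.966,6.120,0.021,0.185,0.845,10.600,0.017
FS-16,0.063,<0.006,0.047,<0.007,0.962,13.000,0.010,0.190,0.320,0.990,<0.015
FS-17,0.063,<0.006,0.080,<0.007,0.967,3.050,0.021,0.123,0.292,2.360,<0.015
FS-18,0.095,<0.006,0.065,<0.007,0.983,3.430,0.015,0.195,1.03,5.820,<0.015
FS-19,0.038,<0.006,0.019,<0.007,0.502,1.580,0.009,0.056,0.103,3.950,<0.015
FS-20,0.066,<0.006,0.030,<0.007,1.000,1.880,0.005,0.119,0.309,2.760,<0.015
FS-21,0.027,<0.006,0.015,<0.007,0.503,0.960,0.002,0.054,0.139,0.300,<0.015
FS-22,0.275,0.095,0.053,<0.007,0.846,168.000,0.048,0.535,7.320,82.900,0.027
FS-23,0.037,<0.006,0.019,<0.007,0.527,2.900,0.004,0.063,0.248,0.384,<0.015
FS-24,0.036,<0.006,0.015,<0.007,0.512,1.450,0.003,0.062,0.100,1340.000,<0.015
FS-25,0.031,<0.006,0.015,<0.007,0.510,0.878,0.002,0.056,0.109,0.439,<0.015
FS-26,0.020,<0.006,0.016,<0.007,0.507,2.010,0.012,0.063,0.109,0.394,<0.015
FS-27,0.035,<0.006,0.016,<0.007,0.514,1.390,0.005,0.085,0.189,1.860,<0.015
FS-28,0.032,<0.006,0.018,<0.007,0.511,3.510,0.006,0.073,0.179,0.954,<0.015
FS-29,0.068,<0.006,0.021,<0.007,0.548,2.740,0.019,0.244,0.230,0.568,<0.015
FS-30,0.056,<0.006,0.026,<0.007,0.492,1.230,0.016,0.176,0.213,0.673,<0.015
FS-31,0.050,<0.006,0.022,<0.007,0.637,6.630,0.007,0.110,0.122,0.492,<0.015
FS-32,0.069,<0.006,0.038,<0.007,0.987,2.670,0.011,0.109,0.230,1.380,<0.015
FS-33,0.075,<0.006,0.022,<0.007,0.538,1.800,0.003,0.098,0.109,0.636,<0.015
FS-34,0.040,<0.006,0.073,<0.007,0.667,21.400,0.065,0.735,0.334,1.260,0.022
FS-35,0.048,<0.006,0.077,<0.007,0.561,20.900,0.070,0.629,0.242,2.470,<0.015
FS-36,0.061,<0.006,0.017,<0.007,0.507,2.380,0.003,0.070,0.114,0.305,<0.015
FS-37,0.045,<0.006,0.023,<0.007,0.554,2.880,0.008,0.185,0.215,1.060,<0.015
FS-38,0.020,<0.006,0.017,<0.007,0.422,0.870,0.003,0.072,0.112,0.334,<0.015
FS-39,0.026,<0.006,0.019,<0.007,0.515,1.380,0.007,0.067,0.137,0.501,<0.015
FS-40,0.027,<0.006,0.014,<0.007,0.494,1.690,0.006,0.050,0.193,0.672,<0.015
FS-41,0.067,<0.006,0.030,<0.007,1.090,2.290,0.005,0.106,0.207,1.040,<0.015
FS-42,0.035,<0.006,0.021,<0.007,0.556,1.290,0.006,0.087,0.162,0.605,<0.015
FS-43,0.036,<0.006,0.020,<0.007,0.515,1.690,0.012,0.088,0.250,1.920,<0.015
FS-44,0.047,<0.006,0.020,<0.007,0.560,275.000,0.024,0.109,0.367,1.120,<0.015
FS-45,0.024,<0.006,0.020,<0.007,0.569,0.667,0.002,0.054,0.094,0.198,<0.015
FS-46,0.055,<0.006,0.031,<0.007,1.030,1.360,0.006,0.101,0.193,0.761,<0.015
FS-47,0.044,<0.006,0.034,<0.007,0.941,1.250,0.006,0.104,0.185,0.666,<0.015
FS-48,0.059,<0.006,0.027,<0.007,0.971,2.170,0.009,0.121,0.283,2.010,0.016
FS-49,0.062,<0.006,0.037,<0.007,1.020,2.820,0.010,0.130,0.297,4.250,0.020
FS-50,0.085,0.010,0.017,<0.007,0.565,6.160,0.016,0.197,1.610,7.290,<0.015
FS-51,0.064,<0.006,0.030,<0.007,0.568,8.040,0.025,0.243,2.560,8.300,<0.015
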