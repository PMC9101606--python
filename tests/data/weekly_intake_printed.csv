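code,Pb,Cd,As,Hg,Ni,Co,Se,Cr,Fe,Cu,Zn
FS-01,8.96,0.42,1.19,0.49,21.35,0.35,1.05,0.008,1.246,0.0329,0.889
FS-02,12.32,0.42,2.03,0.49,52.15,0.35,1.05,0.008,0.103,0.0095,0.131
FS-03,3.99,0.42,1.96,0.49,8.19,0.21,1.05,0.006,0.102,0.0253,0.184
FS-04,5.18,0.42,1.19,0.49,6.51,0.98,134.40,0.014,5.747,1.5680,0.215
FS-05,11.34,0.70,1.05,0.84,9.87,0.42,1.05,0.005,0.091,1.0640,0.159
FS-06,0.42,0.02,0.04,0.02,0.31,0.01,0.12,0.001,0.029,0.0128,0.057
FS-07,1.24,0.06,0.16,0.06,0.89,0.03,0.23,0.002,0.080,0.0199,0.115
FS-08,2.89,0.15,0.44,0.17,2.99,0.22,0.37,0.005,0.402,0.0064,0.134
FS-09,1.05,0.11,0.35,0.12,1.59,0.07,0.37,0.002,0.067,0.0208,0.111
FS-10,20.16,1.47,3.15,1.47,21.21,1.89,3.15,0.015,0.416,0.0378,8.694
FS-11,6.02,0.42,1.33,0.49,3.64,0.49,1.05,0.008,0.104,0.0102,0.062
FS-12,9.77,0.63,1.58,0.74,7.35,1.47,1.58,0.016,105.525,0.0089,0.230
FS-13,6.86,0.84,2.52,1.26,11.48,56.42,2.10,0.073,0.368,0.1071,25.060
FS-14,6.30,1.05,3.85,1.23,12.43,1.05,3.50,0.092,0.443,0.0574,0.331
FS-15,4.69,1.61,2.52,0.49,12.95,1.47,1.19,0.068,0.428,0.0592,0.742
FS-16,0.60,0.06,0.44,0.07,1.80,0.09,0.14,0.009,0.123,0.0030,0.009
FS-17,0.79,0.08,1.01,0.09,1.55,0.26,0.19,0.012,0.038,0.0037,0.030
FS-18,0.90,0.06,0.61,0.07,1.84,0.14,0.14,0.009,0.032,0.0097,0.055
FS-19,0.96,0.15,0.48,0.18,1.41,0.23,0.38,0.013,0.040,0.0026,0.100
FS-20,1.73,0.16,0.79,0.18,3.12,0.13,0.39,0.026,0.049,0.0081,0.072
FS-21,0.57,0.13,0.32,0.15,1.13,0.04,0.32,0.011,0.020,0.0029,0.006
FS-22,3.08,1.06,0.59,0.08,5.99,0.54,0.30,0.009,1.882,0.0820,0.928
FS-23,2.59,0.42,1.33,0.49,4.41,0.28,1.05,0.037,0.203,0.0174,0.027
FS-24,3.15,0.53,1.31,0.61,5.43,0.26,1.31,0.045,0.127,0.0088,117.250
FS-25,3.80,0.74,1.84,0.86,6.86,0.25,1.84,0.062,0.108,0.0134,0.054
FS-26,1.40,0.42,1.12,0.49,4.41,0.84,1.05,0.035,0.141,0.0076,0.028
FS-27,7.35,1.26,3.36,1.47,17.85,1.05,3.15,0.108,0.292,0.0397,0.391
FS-28,9.34,1.75,5.25,2.04,21.31,1.75,4.38,0.149,1.025,0.0523,0.278
FS-29,0.52,0.05,0.16,0.05,1.88,0.15,0.12,0.004,0.021,0.0018,0.004
FS-30,0.22,0.02,0.10,0.03,0.68,0.06,0.06,0.002,0.005,0.0008,0.003
FS-31,0.42,0.05,0.18,0.06,0.92,0.06,0.13,0.005,0.056,0.0010,0.004
FS-32,0.81,0.07,0.45,0.08,1.28,0.13,0.18,0.012,0.031,0.0027,0.016
FS-33,0.26,0.02,0.08,0.02,0.34,0.01,0.05,0.002,0.006,0.0004,0.002
FS-34,0.84,0.13,1.53,0.15,15.44,1.37,0.46,0.014,0.449,0.0070,0.026
FS-35,1.01,0.13,1.62,0.15,13.21,1.47,0.32,0.012,0.439,0.0051,0.052
FS-36,1.49,0.15,0.42,0.17,1.72,0.07,0.37,0.012,0.058,0.0028,0.007
FS-37,0.52,0.07,0.27,0.08,2.14,0.09,0.17,0.006,0.033,0.0025,0.012
FS-38,1.26,0.38,1.07,0.44,4.54,0.19,0.95,0.027,0.055,0.0071,0.021
FS-39,0.82,0.19,0.60,0.22,2.11,0.22,0.47,0.016,0.043,0.0043,0.016
FS-40,4.25,0.95,2.21,1.10,7.88,0.95,2.36,0.078,0.266,0.0304,0.106
FS-41,16.60,1.49,7.43,1.73,26.27,1.24,3.72,0.270,0.567,0.0513,0.258
FS-42,3.68,0.63,2.21,0.74,9.14,0.63,1.58,0.058,0.135,0.0170,0.064
FS-43,7.56,1.26,4.20,1.47,18.48,2.52,3.15,0.108,0.355,0.0525,0.403
FS-44,3.29,0.42,1.40,0.49,7.63,1.68,1.05,0.039,19.250,0.0257,0.078
FS-45,1.68,0.42,1.40,0.49,3.78,0.14,1.05,0.040,0.047,0.0066,0.014
FS-46,5.78,0.63,3.26,0.74,10.61,0.63,1.58,0.108,0.143,0.0203,0.080
FS-47,4.62,0.63,3.57,0.74,10.92,0.63,1.58,0.099,0.131,0.0194,0.070
FS-48,13.42,1.37,6.14,1.59,27.53,2.05,3.64,0.221,0.494,0.0644,0.457
FS-49,6.51,0.63,3.89,0.74,13.65,1.05,2.10,0.107,0.296,0.0312,0.446
FS-50,8.93,1.05,1.79,0.74,20.69,1.68,1.58,0.059,0.647,0.1691,0.765
FS-51,6.72,0.63,3.15,0.74,25.52,2.63,1.58,0.060,0.844,0.2688,0.872
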