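code,BMDL01,NOAEL,BMDL10,BMDL05,LOAEL,DNEL
FS-01,0.380,1.000,0.990,0.995,1.000,0.692
FS-02,0.292,1.000,0.990,0.995,1.000,0.699
FS-03,0.300,1.000,0.993,0.996,1.000,0.784
FS-04,0.380,1.000,0.983,0.990,1.000,0.471
FS-05,0.395,0.999,0.994,0.997,1.000,0.622
FS-06,0.970,1.000,1.000,1.000,1.000,0.824
FS-07,0.832,1.000,0.999,0.999,1.000,0.814
FS-08,0.551,1.000,0.994,0.997,1.000,0.804
FS-09,0.841,1.000,0.998,0.999,1.000,0.811
FS-10,0.175,0.999,0.981,0.990,1.000,0.551
FS-11,0.365,1.000,0.990,0.995,1.000,0.806
FS-12,0.339,1.000,0.980,0.989,1.000,0.625
FS-13,0.241,0.999,0.906,0.948,0.992,0.549
FS-14,0.102,0.999,0.881,0.934,1.000,0.725
FS-15,0.241,1.000,0.913,0.952,1.000,0.698
FS-16,0.900,1.000,0.989,0.994,1.000,0.823
FS-17,0.812,1.000,0.985,0.992,1.000,0.825
FS-18,0.837,1.000,0.989,0.994,1.000,0.821
FS-19,0.841,1.000,0.984,0.991,1.000,0.823
FS-20,0.692,1.000,0.967,0.982,1.000,0.816
FS-21,0.917,1.000,0.987,0.993,1.000,0.827
FS-22,0.507,1.000,0.989,0.994,1.000,0.659
FS-23,0.504,1.000,0.953,0.974,1.000,0.798
FS-24,0.421,1.000,0.943,0.968,1.000,0.634
FS-25,0.312,0.999,0.920,0.956,1.000,0.789
FS-26,0.707,1.000,0.955,0.975,1.000,0.805
FS-27,0.153,0.999,0.861,0.923,1.000,0.722
FS-28,0.000,0.999,0.807,0.894,1.000,0.674
FS-29,0.942,1.000,0.995,0.997,1.000,0.828
FS-30,0.994,1.000,0.998,0.999,1.000,0.832
FS-31,0.955,1.000,0.994,0.997,1.000,0.829
FS-32,0.867,1.000,0.986,0.992,1.000,0.827
FS-33,0.990,1.000,0.998,0.999,1.000,0.833
FS-34,0.750,1.000,0.983,0.990,1.000,0.778
FS-35,0.715,1.000,0.986,0.992,1.000,0.784
FS-36,0.767,1.000,0.985,0.992,1.000,0.824
FS-37,0.930,1.000,0.993,0.996,1.000,0.826
FS-38,0.734,1.000,0.966,0.981,1.000,0.809
FS-39,0.850,1.000,0.980,0.989,1.000,0.821
FS-40,0.273,0.999,0.900,0.945,1.000,0.765
FS-41,0.000,0.999,0.650,0.807,1.000,0.686
FS-42,0.273,1.000,0.925,0.959,1.000,0.784
FS-43,0.066,0.999,0.860,0.923,1.000,0.711
FS-44,0.390,1.000,0.950,0.972,1.000,0.624
FS-45,0.635,1.000,0.949,0.972,1.000,0.811
FS-46,0.164,1.000,0.860,0.923,1.000,0.778
FS-47,0.132,1.000,0.872,0.930,1.000,0.778
FS-48,0.000,0.999,0.714,0.843,1.000,0.675
FS-49,0.098,1.000,0.862,0.924,1.000,0.749
FS-50,0.317,1.000,0.924,0.958,1.000,0.623
FS-51,0.175,1.000,0.923,0.958,1.000,0.555
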