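sample,a254,pe_srfa,pe_ppfa,decision
AFF-01,0.212,32.9,32.1,Fulvic
AFF-02,0.168,76.1,77.6,Non-fulvic
AFF-03,0.130,21.5,17.7,Fulvic
AFF-04,0.182,49.2,49.4,Fulvic
AFF-05,0.299,24.0,22.9,Fulvic
AFF-06,2.145,16.3,16.3,Fulvic
AFF-07,0.130,39.8,39.4,Fulvic
ACFP-01,0.266,61,62,Fulvic
ACFP-02,0.160,41,40,Fulvic
ACFP-03,0.158,58,59,Fulvic
ACFP-04,0.237,34,33,Fulvic
ACFP-05,0.180,32,29,Fulvic
ACFP-06,0.350,31,31,Fulvic
ACFP-07,0.264,49,49,Fulvic
ACFP-08,0.235,50,51,Fulvic
ACFP-09,0.229,82,91,Fulvic
ACFP-10,0.522,149,159,Non-fulvic
ACFP-11,0.000,174,165,Non-fulvic
ACFP-12,0.009,71,68,Non-fulvic
ACFP-13,0.000,945,841,Non-fulvic
ACFP-14,0.267,146,146,Non-fulvic
ACFP-15,0.088,74,71,Non-fulvic
ACFP-16,0.107,68,64,Fulvic
ACFP-17,0.012,68,67,Non-fulvic
ACFP-18,0.295,87,84,Non-fulvic
ACFP-19,0.048,92,91,Non-fulvic
ACFP-20,1.479,339,335,Non-fulvic
ACFP-21,3.019,131,129,Non-fulvic
ANHM-01,0.005,38.8,38.7,Non-fulvic
ANHM-02,0.002,300.5,284.0,Non-fulvic
ANHM-03,0.000,118.7,114.6,Non-fulvic
ANHM-04,0.009,158.1,161.0,Non-fulvic
ANHM-05,0.080,76.9,79.3,Non-fulvic
ANHM-06,0.007,177.3,182.4,Non-fulvic
AHSE-01,0.529,102.1,109.2,Non-fulvic
AHSE-02,0.500,95.5,102.9,Non-fulvic
AHSE-03,0.915,98.6,105.2,Non-fulvic
AHSE-04,0.807,91.3,99.2,Non-fulvic
ANOM-01,0.586,28.0,,Fulvic
ANOM-02,0.221,6.1,,Fulvic
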