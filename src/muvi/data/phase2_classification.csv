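sample,a254,pe_srfa,pe_ppfa,decision
AFF-01,0.247,40.5,41.4,Fulvic
AFF-02,0.327,49.3,43.8,Fulvic
AFF-03,0.175,31.3,24.0,Fulvic
AFF-04,0.407,31.3,27.7,Fulvic
ACFP-01,0.435,42.2,39.5,Fulvic
ACFP-02,0.265,25.0,25.0,Fulvic
ACFP-03,0.207,45.9,44.4,Fulvic
ACFP-04,0.266,33.2,32.0,Fulvic
ANOM-01,0.140,30.0,30.1,Fulvic
BFF-01,0.247,30.5,20.2,Fulvic
BFF-02,0.191,16.7,18.9,Fulvic
BFF-03,0.173,40.7,38.6,Fulvic
BFF-04,0.201,57.0,57.7,Fulvic
BCFP-01,0.212,47.1,47.6,Fulvic
BCFP-02,0.175,40.9,38.8,Fulvic
BCFP-03,0.180,46.9,47.5,Fulvic
BCFP-04,0.120,46.5,47.1,Fulvic
BCFP-05,0.351,26.3,27.6,Fulvic
BHFA-01,0.175,20.6,20.4,Fulvic
BNHM-01,0.045,94.7,86.2,Non-fulvic
BNHM-02,0.074,136.3,123.2,Non-fulvic
BNHM-03,0.072,29.7,30.0,Non-fulvic
BNHM-04,0.056,121.0,107.3,Non-fulvic
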