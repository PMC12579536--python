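name,s275,s350,a254,a280,a325,a355,a412,a440,sr,e2e3
SRFA,0.01,0.02,0.54,0.40,0.22,0.14,0.05,0.03,0.70,4.74
PPFA,0.013,0.016,0.53,0.36,0.16,0.13,0.051,0.03,0.8,4.7
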