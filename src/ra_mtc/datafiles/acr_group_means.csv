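source,m1,m2,m3,m4
meanACR,0.17,0.41,0.57,0.72
ACRhybrid,0.10,0.41,0.59,0.77
control,0.00,0.35,0.60,0.85
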