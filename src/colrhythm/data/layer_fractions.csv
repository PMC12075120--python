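layer,fraction
L1,0.0192574218
L2/3,0.291088453
L4,0.237625904
L5,0.17425693
L6,0.2972
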