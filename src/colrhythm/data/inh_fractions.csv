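layer,PV,SST,VIP
L2/3,0.295918,0.214286,0.489796
L4,0.552381,0.295238,0.152381
L5,0.485714,0.428571,0.085714
L6,0.458333,0.458333,0.083333
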