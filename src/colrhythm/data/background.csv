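group,rate_hz
VIP1,650
E2/3,930
PV2/3,1460
SST2/3,870
VIP2/3,1405
E4,890
PV4,1980
SST4,2105
VIP4,240
E5,4740
PV5,930
SST5,530
VIP5,870
E6,1770
PV6,1170
SST6,885
VIP6,1620
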