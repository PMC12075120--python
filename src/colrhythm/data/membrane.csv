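group,C_m_pF,g_L_nS,tau_ref_ms,V_rest_mV,V_th_mV
VIP1,37.11,4.07,3.5,-65.5,-40.20
E2/3,123.41,2.47,3,-80.97,-40.53
PV2/3,70.95,9.49,1.26,-82.35,-56.32
SST2/3,82.34,3.17,1.85,-69.16,-39.95
VIP2/3,41.23,6.4,2.75,-67.94,-41.34
E4,80.16,5.16,4.4,-72.53,-47.63
PV4,81.21,9.19,1.5,-70.45,-44.23
SST4,132.86,7.96,2.2,-74.2,-44.07
VIP4,40.3,1.87,2.4,-63.14,-40.89
E5,149.43,16.66,4.25,-68.28,-40.55
PV5,70.9,5.21,1.85,-77.5,-51.2
SST5,52.32,3.43,1.9,-70.01,-47.38
VIP5,59.29,6.52,2.55,-72.00,-51.2
E6,99.96,5.88,3.3,-77.5,-42.31
PV6,49.65,6.86,1.65,-76.42,-49.06
SST6,96.09,2.99,2.1,-62.99,-37.19
VIP6,65.87,6.09,2.85,-78.85,-44.81
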