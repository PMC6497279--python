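station_id,depth_m,shannon_h,hills_n2
BT1,18.29,1.955,5.521
BT2,19.51,1.951,4.354
BT3,20.73,1.251,2.275
BT4,20.12,1.866,5.245
BT5,27.43,2.136,6.779
BT6,27.13,0.441,1.210
BT7,27.13,1.333,2.479
BT8,29.26,0.825,1.502
BT9,26.21,0.330,1.129
BT10,26.52,1.539,3.113
BT11,26.52,1.512,3.334
BT12,25.30,0.778,1.536
BT13,26.21,1.506,2.910
BT14,28.96,1.092,1.923
BT15,28.96,0.152,1.050
All,,1.628,2.787
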