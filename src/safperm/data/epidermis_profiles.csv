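compound,compartment,r_inter_s_per_m,r_trans_s_per_m
CAF,SC,2.15e12,4.07e7
CAF,SG,1.26e8,1.34e7
CAF,SS,2.86e8,2.26e7
CAF,SB,1.98e7,4.58e6
CHA,SC,8.20e16,1.76e8
CHA,SG,5.14e8,5.13e11
CHA,SS,1.17e9,8.54e11
CHA,SB,8.07e7,1.71e11
FA,SC,2.55e11,3.23e7
FA,SG,1.23e8,1.63e6
FA,SS,2.80e8,2.91e6
FA,SB,1.94e7,6.50e5
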