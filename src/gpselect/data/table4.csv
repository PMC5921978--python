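process,n_target,mean_3y,sd_3y,mean_5y,sd_5y,fillable
process_2015,1000,636,15,861,8.0,True
process_2015,1500,939,17,1281,8.9,True
process_2015,2000,1227,20,1694,9.7,True
process_2015,2500,1491,18,2094,12,True
process_2015,3000,1693,21,2448,14,True
process_2015,3500,,,,,False
process_2015,4000,,,,,False
random,1000,515,15,791,13,True
random,1500,774,22,1185,17,True
random,2000,1034,27,1580,22,True
random,2500,1293,30,1976,25,True
random,3000,1551,31,2370,28,True
random,3500,1811,36,2764,30,True
random,4000,2056,38,3138,39,True
stage2_only,1000,673,14,881,5.9,True
stage2_only,1500,985,17,1308,7.2,True
stage2_only,2000,1283,21,1726,8.7,True
stage2_only,2500,1553,21,2217,10,True
stage2_only,3000,1791,23,2512,15,True
stage2_only,3500,1983,28,2873,21,True
stage2_only,4000,2115,32,3178,37,True
stage3_only,1000,596,12,842,8.4,True
stage3_only,1500,886,17,1256,11,True
stage3_only,2000,1171,19,1668,11,True
stage3_only,2500,1442,20,2072,13,True
stage3_only,3000,1692,23,2466,15,True
stage3_only,3500,1910,26,2841,19,True
stage3_only,4000,2091,32,3615,34,True
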