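dataset,n_binary,n_ordinal,n_mwu,n_ttest,mult_binary,mult_ordinal,mult_mwu,mult_ttest
1,4528,4052,1194,1196,1,0.89,0.26,0.26
2,17986,11970,3326,3904,1,0.67,0.18,0.22
3,15292,10072,2744,2828,1,0.66,0.18,0.18
4,5436,2382,704,898,1,0.44,0.13,0.17
5,25090,8666,2426,3362,1,0.35,0.097,0.13
6,30450,10164,2958,5070,1,0.33,0.097,0.17
13,13510,12610,3806,3754,1,0.93,0.28,0.28
18,23090,22110,6486,7194,1,0.96,0.28,0.31
30,15934,1582,442,566,1,0.099,0.028,0.036
31,6934,1952,608,802,1,0.28,0.088,0.12
32,115114,63792,17482,19952,1,0.55,0.15,0.17
33,15198,10862,3388,3450,1,0.71,0.22,0.23
55,37646,37456,10924,12186,1,0.99,0.29,0.32
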