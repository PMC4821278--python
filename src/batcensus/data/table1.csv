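day,N_v,N_N,N_S,S_v,S_N,S_S
1,16427,15560,14656,NA,NA,NA
2,8165,8574,8404,24064,17990,16630
3,15886,15087,14302,67163,86933,76311
4,13693,13966,13240,29322,29813,27248
5,11515,7642,7316,32498,26478,24052
6,8408,10145,9514,24150,49200,43216
7,8455,10210,9285,45827,44954,40088
8,14430,8982,8416,46548,27035,24604
9,20823,13987,12886,36324,26101,22985
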