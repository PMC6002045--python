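rank,features,rm,auc_cv_mean,auc_cv_sd,or0,or10
1,LH,1.0,0.904,0.023,0.0059,0.1016
2,LQP,2.0,0.902,0.024,0.0059,0.1033
3,LQPT,2.0,0.904,0.024,0.0059,0.1075
4,LH,2.0,0.902,0.024,0.0173,0.1078
5,LQP,1.0,0.901,0.024,0.0110,0.1127
6,LQH,2.0,0.901,0.025,0.0118,0.1127
7,LQH,1.5,0.903,0.024,0.0056,0.1131
8,LQPH,1.5,0.903,0.023,0.0059,0.1150
9,LQPH,2.0,0.898,0.024,0.0110,0.1196
10,LQPTH,1.5,0.906,0.024,0.0167,0.1199
11,LH,1.5,0.904,0.025,0.0114,0.1203
12,LQP,1.5,0.899,0.024,0.0056,0.1206
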