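rank,features,rm,auc_cv_mean,auc_cv_sd,or0,or10
1,LQPH,1.0,0.900,0.017,0.0071,0.1086
2,LQPTH,2.0,0.896,0.017,0.0048,0.1108
3,LQH,1.0,0.889,0.017,0.0096,0.1108
4,LQP,2.0,0.886,0.017,0.0024,0.113
5,LQP,1.0,0.886,0.017,0.0048,0.1134
6,LQPH,2.0,0.896,0.017,0.0024,0.1155
7,LQPH,1.5,0.897,0.016,0.0048,0.1155
8,LH,2.0,0.884,0.017,0.0024,0.1158
9,LQH,2.0,0.882,0.017,0.0024,0.1204
10,LH,1.0,0.892,0.017,0.0024,0.1205
11,LQPTH,1.5,0.896,0.017,0.0048,0.1226
12,LQH,1.5,0.884,0.017,0.0048,0.1227
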