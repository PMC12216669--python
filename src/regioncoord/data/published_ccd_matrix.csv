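county,y2020,y2021,y2022
Xiaoshan,0.647,0.850,0.794
Yuhang,0.739,0.569,0.673
Linping,0.448,0.705,0.605
Qiantang,0.448,0.471,0.453
Fuyang,0.485,0.599,0.557
Linan,0.521,0.520,0.487
Tonglu,0.404,0.498,0.525
Chunan,0.323,0.413,0.439
Jiande,0.406,0.496,0.516
Haishu,0.654,0.745,0.807
Jiangbei,0.524,0.634,0.621
Beilun,0.539,0.655,0.613
Zhenhai,0.541,0.592,0.696
Yinzhou,0.764,0.720,0.864
Fenghua,0.535,0.565,0.620
Xiangshan,0.377,0.640,0.567
Ninghai,0.532,0.546,0.571
Yuyao,0.548,0.695,0.800
Cixi,0.631,0.626,0.802
Lucheng,0.737,0.651,0.773
Longwan,0.472,0.711,0.635
Ouhai,0.552,0.741,0.644
Dongtou,0.259,0.340,0.240
Yongjia,0.442,0.572,0.657
Pingyang,0.487,0.378,0.571
Cangnan,0.406,0.547,0.553
Wencheng,0.233,0.239,0.221
Taishun,0.197,0.276,0.224
Ruian,0.572,0.534,0.690
Yueqing,0.603,0.530,0.736
Longgang,0.417,0.448,0.413
Nanhu,0.587,0.620,0.555
Xiuzhou,0.419,0.487,0.498
Jiashan,0.494,0.506,0.585
Haiyan,0.445,0.465,0.478
Haining,0.561,0.649,0.680
Pinghu,0.525,0.455,0.569
Tongxiang,0.472,0.583,0.610
Wuxing,0.591,0.645,0.671
Nanxun,0.386,0.500,0.570
Deqing,0.439,0.551,0.561
Changxing,0.465,0.521,0.590
Anji,0.417,0.527,0.556
Yuecheng,0.616,0.566,0.644
Keqiao,0.599,0.615,0.731
Shangyu,0.504,0.587,0.641
Xinchang,0.365,0.530,0.455
Zhuji,0.534,0.696,0.741
Shengzhou,0.474,0.440,0.569
Wucheng,0.463,0.588,0.594
Jindong,0.374,0.378,0.471
Wuyi,0.318,0.386,0.421
Pujiang,0.380,0.400,0.438
Panan,0.278,0.286,0.380
Lanxi,0.417,0.373,0.478
Yiwu,0.631,0.523,0.740
Dongyang,0.495,0.525,0.559
Yongkang,0.454,0.543,0.532
Kecheng,0.436,0.545,0.577
Qujiang,0.339,0.370,0.455
Changshan,0.264,0.361,0.393
Kaihua,0.266,0.245,0.326
Longyou,0.312,0.442,0.493
Jiangshan,0.416,0.364,0.456
Dinghai,0.446,0.452,0.491
Putuo,0.431,0.444,0.426
Daishan,0.212,0.262,0.245
Shengsi,0.257,0.439,0.311
Jiaojiang,0.609,0.512,0.603
Huangyan,0.617,0.382,0.520
Luqiao,0.558,0.517,0.539
Sanmen,0.537,0.347,0.321
Tiantai,0.537,0.483,0.438
Xianju,0.479,0.382,0.321
Wenling,0.458,0.581,0.690
Linhai,0.679,0.603,0.651
Yuhuan,0.617,0.585,0.641
Liandu,0.622,0.526,0.600
Qingtian,0.507,0.387,0.441
Jinyun,0.629,0.434,0.444
Suichang,0.301,0.390,0.379
Songyang,0.300,0.373,0.393
Yunhe,0.341,0.333,0.325
Qingyuan,0.233,0.224,0.310
Jingning,0.226,0.158,0.246
Longquan,0.486,0.276,0.372
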