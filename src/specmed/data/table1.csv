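sample_no,trial,f710_690,f1010_940,f_combined,dmv,cg_dmv,chg_dmv,sv,time_days
1,M1,0.0012,0.0443,0.0455,1.6210,0.4636,1.1583,3.7058,21
2,M1,0.0021,0.0267,0.0288,1.3900,0.2325,1.1588,2.5488,21
3,M1,0.0018,0.0371,0.0389,1.3900,0.2315,1.1584,2.5479,21
4,M1,0.0014,0.0317,0.0332,1.3900,0.2315,1.1584,2.7794,21
5,M1,0.0011,0.0388,0.0399,1.6210,0.4630,1.1583,3.2423,21
6,M2,0.0010,0.0283,0.0293,1.6220,0.4637,1.1585,2.5481,28
7,M2,0.0015,0.0287,0.0302,1.6220,0.4650,1.1584,2.3171,28
8,M2,0.0018,0.0322,0.0339,1.3900,0.4640,0.9268,2.5482,28
9,M3,0.0014,0.0274,0.0288,1.3900,0.4640,0.9268,2.5482,35
10,M3,0.0014,0.0264,0.0279,1.6210,0.4636,1.1583,3.7058,35
11,M3,0.0008,0.0454,0.0461,1.6210,0.4637,1.1584,3.9377,35
12,M3,0.0018,0.0263,0.0281,1.3900,0.4640,0.9268,2.5482,35
13,M3,0.0019,0.0255,0.0275,1.3830,0.4616,0.9224,4.3802,35
14,M4,0.0011,0.0282,0.0293,1.3900,0.4640,0.9268,2.5482,28
15,M4,0.0013,0.0325,0.0338,1.3900,0.4640,0.9268,2.3166,28
16,M5,0.0010,0.0329,0.0339,1.3900,0.4637,0.9268,2.5482,35
17,M5,0.0009,0.0484,0.0493,1.3900,0.4630,0.9266,3.7055,35
18,M5,0.0009,0.0483,0.0491,1.6220,0.6952,0.9271,3.4748,35
19,M5,0.0018,0.0294,0.0312,1.8530,0.6954,1.1582,3.7057,35
20,M6,0.0011,0.0353,0.0364,0.9270,0.0000,0.9271,2.5487,21
21,M6,0.0013,0.0343,0.0356,1.3900,0.4640,0.9268,2.5482,21
22,M6,0.0016,0.0238,0.0254,0.9270,0.0000,0.9268,2.5484,21
23,M6,0.0018,0.0311,0.0329,1.1580,0.2323,0.9268,2.5483,21
24,M6,0.0015,0.0331,0.0346,1.1580,0.2315,0.9271,2.3167,21
25,M7,0.0014,0.0268,0.0283,1.8530,0.6944,1.1581,4.6315,35
26,M7,0.0009,0.0482,0.0492,1.6210,0.4630,1.1584,2.5478,35
27,M7,0.0010,0.0373,0.0383,1.3900,0.4630,0.9266,3.9370,35
28,M8,0.0009,0.0440,0.0449,0.0000,0.0000,0.0000,13.5169,21
29,M8,0.0004,0.0533,0.0537,0.0000,0.0000,0.0000,13.5170,21
30,M8,0.0014,0.0426,0.0440,0.0000,0.0000,0.0000,14.0089,21
31,M9,0.0013,0.0441,0.0454,2.0840,0.9267,1.1582,4.4006,28
32,M9,0.0015,0.0361,0.0377,1.1580,0.2320,0.9268,2.7798,28
33,M9,0.0013,0.0388,0.0400,1.1580,0.2320,0.9268,2.7798,28
34,M9,0.0016,0.0335,0.0351,1.1580,0.2320,0.9268,2.5486,28
35,M9,0.0019,0.0223,0.0243,2.0940,0.9320,1.1651,3.4931,28
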