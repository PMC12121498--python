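mode,tG+g-_MP2,tG+g-_PES,g+G+g-_MP2,g+G+g-_PES,g-G+g-_MP2,g-G+g-_PES,tTt_MP2,tTt_PES,g+Tg-_MP2,g+Tg-_PES
1,168,170,168,167,100,-67,116,132,141,145
2,247,216,292,301,159,167,217,190,250,192
3,329,332,327,326,321,326,230,209,268,223
4,420,407,452,459,428,432,291,295,296,285
5,523,529,536,531,528,530,481,483,475,468
6,887,889,878,874,881,880,839,842,803,787
7,904,905,897,900,885,889,1009,1046,1027,1043
8,1066,1071,1059,1061,1051,1058,1076,1074,1074,1074
9,1100,1098,1073,1073,1063,1073,1094,1090,1090,1083
10,1130,1135,1122,1121,1126,1123,1167,1168,1109,1107
11,1178,1207,1204,1215,1198,1200,1190,1236,1140,1154
12,1269,1277,1246,1250,1257,1280,1235,1241,1320,1337
13,1296,1314,1374,1360,1383,1401,1288,1306,1339,1343
14,1384,1390,1377,1379,1389,1403,1319,1328,1370,1364
15,1420,1429,1406,1405,1404,1414,1409,1427,1404,1381
16,1455,1465,1435,1437,1422,1428,1487,1513,1433,1429
17,1516,1519,1511,1514,1508,1513,1541,1545,1521,1507
18,1524,1525,1521,1519,1512,1526,1551,1549,1535,1535
19,3053,3056,3026,3027,3071,3069,3057,3065,3067,3067
20,3058,3064,3070,3073,3074,3077,3064,3066,3076,3075
21,3114,3118,3134,3136,3140,3142,3102,3104,3124,3127
22,3149,3148,3159,3160,3148,3150,3127,3130,3150,3149
23,3808,3831,3794,3815,3845,3856,3857,3870,3840,3856
24,3856,3871,3831,3847,3846,3876,3858,3878,3842,3869
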