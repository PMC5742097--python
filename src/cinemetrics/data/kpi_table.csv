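movie,premiere,wknd1,wknd2,wknd3,wknd4,wknd5,wknd6,wknd7,wknd8
1,1.0975,0.4563,0.2372,0.1373,0.0866,0.0691,0.0489,0.0386,0.0184
2,0.3857,0.1907,0.1028,0.0717,0.0465,0.0342,0.0232,0.0180,0.0102
3,0.6737,0.2872,0.1867,0.0468,0.0086,0.0020,0.0006,0.0021,0.0007
4,0.5548,0.2478,0.1477,0.1012,0.1005,0.0609,0.0477,0.0308,0.0222
5,0.6207,0.3409,0.1764,0.0979,0.0505,0.0324,0.0166,0.0084,0.0051
6,0.5246,0.2282,0.1338,0.0953,0.0521,0.0388,0.0212,0.0116,0.0062
7,0.1034,0.0433,0.0159,0.0059,0.0013,0.0009,0.0007,0.0004,0.0003
8,0.3399,0.1318,0.0587,0.0181,0.0056,0.0007,0.0028,0.0020,0.0011
9,0.4271,0.2133,0.0986,0.0511,0.0255,0.0117,0.0063,0.0051,0.0031
10,0.2980,0.1101,0.0575,0.0213,0.0085,0.0064,0.0028,0.0021,0.0028
11,0.3469,0.1578,0.0761,0.0510,0.0293,0.0181,0.0066,0.0029,0.0045
12,0.3006,0.1514,0.0885,0.0589,0.0372,0.0137,0.0045,0.0018,0.0022
13,0.3938,0.1772,0.0577,0.0167,0.0086,0.0029,0.0013,0.0008,0.0026
14,0.2704,0.1203,0.0640,0.0274,0.0103,0.0045,0.0026,0.0015,0.0018
15,0.5529,0.1628,0.0758,0.0491,0.0308,0.0166,0.0095,0.0051,0.0036
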