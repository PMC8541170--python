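model,prescription,energy,carbohydrate,fiber,protein,animal_protein,plant_protein,tryptophan,threonine,isoleucine,leucine,lysine,methionine_cysteine,phenylalanine_tyrosine,valine,histidine,fat,epa_dha,sodium,potassium,phosphorus,p_prot_printed,calcium,magnesium,copper,manganese,iron,zinc,thiamine,riboflavin,niacin,pyridoxine,folate,cobalamin
conventional,0.5,2016,300,19,36,15,21,409,1377,1608,2678,2226,1333,2715,1895,930,77,263,1088,1936,525,14.5,264,222,838,6.1,11,5,1.2,0.7,15,1.3,483,2.3
lacto_ovo,0.5,2071,301,19,36,13,23,441,1353,1653,2866,2056,1384,3022,2075,875,83,21,573,1952,670,18.6,557,230,930,6.1,13,6,1.2,1.1,11,1.1,529,1.3
plado,0.5,2047,308,21,36,11,25,409,1359,1586,2663,2147,1279,2738,1872,908,77,260,1082,2003,563,15.5,341,237,965,6.5,13,5,1.2,0.7,14,1.3,532,2.2
ovo,0.5,2078,311,23,36,6,30,417,1326,1579,2667,1934,1257,2867,1962,857,80,21,611,1992,632,17.7,457,243,1101,6.7,15,6,1.2,0.9,11,1.2,613,0.6
lacto,0.5,2090,312,23,36,8,28,442,1323,1613,2807,2006,1213,2953,1979,895,80,0,692,2114,705,19.4,634,248,1016,6.4,14,6,1.3,1.0,11,1.1,584,0.8
vegan,0.5,2098,324,27,36,0,36,408,1293,1531,2589,1906,1095,2779,1833,881,78,0,548,2149,646,18.0,551,269,1256,7.3,17,6,1.3,0.7,12,1.2,674,0.0
conventional,0.6,2059,300,19,43,22,21,487,1681,1927,3240,2861,1612,3218,2251,1134,78,537,1120,2093,606,14.1,270,233,854,6.1,11,5,1.2,0.8,17,1.4,484,5.3
lacto_ovo,0.6,2145,302,19,42,19,23,524,1631,1989,3410,2513,1710,3612,2505,1029,88,42,643,2019,766,18.1,584,236,981,6.1,14,6,1.2,1.3,11,1.2,552,1.9
plado,0.6,2088,315,23,42,12,30,488,1611,1879,3136,2601,1462,3234,2171,1089,77,279,758,2135,651,15.4,486,260,1122,6.9,15,6,1.2,0.8,15,1.3,584,3.1
ovo,0.6,2100,298,23,42,13,29,500,1604,1915,3211,2391,1583,3457,2391,1011,85,42,681,2009,725,17.2,484,247,1133,6.2,16,6,1.3,1.1,11,1.3,624,1.3
lacto,0.6,2140,306,24,43,11,32,540,1610,1948,3396,2544,1411,3561,2346,1108,86,0,728,2212,818,19.0,812,266,1100,6.2,16,7,1.3,1.1,11,1.2,604,1.1
vegan,0.6,2138,325,32,42,0,42,470,1520,1802,3035,2326,1243,3258,2121,1054,79,0,551,2311,759,18.0,604,294,1434,7.2,20,7,1.4,0.7,12,1.3,770,0.0
conventional,0.7,2077,295,19,50,29,21,567,1970,2288,3753,3443,1889,3721,2590,1346,79,543,1135,2121,644,12.9,273,238,857,5.9,12,5,1.2,0.8,19,1.5,481,5.3
lacto_ovo,0.7,2170,294,20,50,25,25,623,1919,2374,4119,3112,2008,4315,2948,1245,91,42,626,2163,936,18.8,796,252,1012,5.5,14,7,1.3,1.5,11,1.2,566,2.5
plado,0.7,2180,318,27,50,15,35,572,1923,2250,3718,3180,1714,3849,2530,1318,82,282,1106,2282,765,15.2,517,290,1313,7.0,17,7,1.3,0.8,16,1.5,668,3.1
ovo,0.7,2146,299,28,49,13,36,574,1863,2223,3715,2862,1753,3999,2718,1206,87,42,685,2183,846,17.3,569,275,1329,6.3,19,7,1.4,1.1,12,1.4,722,1.3
lacto,0.7,2185,309,28,50,14,36,606,1846,2276,3970,3036,1664,4143,2719,1288,87,0,492,2458,981,19.6,891,292,1241,6.0,17,8,1.4,1.2,12,1.3,700,1.4
vegan,0.7,2181,325,36,49,0,49,545,1765,2090,3501,2756,1407,3761,2421,1233,81,0,558,2486,866,17.9,724,324,1621,7.3,23,8,1.5,0.7,13,1.4,843,0.0
conventional,0.8,2083,282,19,56,35,21,641,2243,2582,4239,3989,2132,4175,2913,1567,83,603,1151,2157,694,12.4,277,242,850,5.4,12,6,1.3,0.8,20,1.6,470,5.8
lacto_ovo,0.8,2195,287,25,56,25,31,689,2160,2659,4590,3550,2166,4821,3252,1425,93,42,900,2308,1054,18.7,851,279,1188,5.2,17,8,1.4,1.5,11,1.3,655,2.5
plado,0.8,2143,299,30,57,17,40,638,2164,2526,4182,3652,1894,4311,2839,1493,83,400,1114,2406,861,15.2,561,305,1395,6.2,19,7,1.4,0.8,17,1.6,708,3.8
ovo,0.8,2189,300,32,55,13,42,649,2108,2511,4181,3291,1916,4502,3018,1385,89,42,692,2357,954,17.2,689,304,1516,6.3,22,8,1.5,1.1,12,1.5,795,1.3
lacto,0.8,2229,311,31,55,14,41,671,2056,2524,4368,3399,1806,4574,2972,1441,89,0,497,2585,1069,19.3,1006,316,1404,6.1,20,9,1.5,1.2,12,1.4,759,1.4
vegan,0.8,2227,327,40,55,0,55,619,2024,2399,4005,3226,1576,4302,2748,1428,83,0,561,2660,988,17.8,809,352,1817,7.3,26,9,1.6,0.8,13,1.5,941,0.0
conventional,1.0,2140,286,23,70,44,26,801,2823,3228,5325,5062,2626,5279,3631,1999,81,743,1059,2471,854,12.2,320,283,997,5.3,14,7,1.6,1.0,24,1.8,537,7.3
lacto_ovo,1.0,2220,292,32,71,25,46,865,2687,3314,5711,4520,2560,5983,3943,1838,89,42,691,2670,1258,17.8,1173,346,1551,5.5,23,10,1.6,1.6,13,1.5,797,2.5
plado,1.0,2096,289,34,70,23,47,792,2660,3113,5085,4461,2244,5268,3468,1833,77,406,882,2701,981,14.1,682,350,1536,5.6,22,8,1.6,0.9,20,1.8,746,4.8
ovo,1.0,2273,302,40,69,13,56,800,2599,3073,5127,4053,2204,5552,3648,1731,92,42,786,2745,1160,16.8,830,373,1867,6.1,27,10,1.8,1.2,14,1.7,925,2.3
lacto,1.0,2224,315,41,69,13,56,818,2547,3137,5449,4385,2166,5672,3645,1850,81,0,559,2988,1281,18.5,1241,385,1769,6.1,26,10,1.8,1.2,14,1.6,915,1.2
vegan,1.0,2295,335,48,70,0,70,790,2562,3011,5024,4043,1905,5441,3408,1801,81,0,658,3045,1199,17.1,1023,428,2224,7.5,31,11,1.9,0.8,15,1.8,1065,1.0
conventional,1.1,2097,286,25,77,50,27,874,3095,3588,5864,5636,2933,5796,4022,2188,73,805,1107,2602,899,11.7,326,289,988,5.1,14,7,1.6,1.1,24,1.9,554,7.7
lacto_ovo,1.1,2265,300,34,78,25,53,976,3001,3714,6339,5023,2849,6671,4400,2046,87,42,749,2909,1363,17.4,1328,372,1670,5.8,25,11,1.7,1.8,14,1.6,838,2.7
plado,1.1,2142,297,38,79,25,54,896,3020,3529,5776,5140,2497,5969,3930,2095,75,523,894,3003,1129,14.3,796,384,1728,5.9,25,9,1.8,0.9,21,2.0,840,5.4
ovo,1.1,2247,308,42,76,15,61,891,2886,3443,5705,4549,2476,6182,4065,1930,83,42,828,2937,1237,16.2,971,397,2000,6.5,29,10,1.8,1.3,15,1.8,965,2.3
lacto,1.1,2306,331,45,77,14,63,925,2864,3512,6041,4891,2374,6316,4040,2065,80,0,583,3317,1434,18.5,1413,423,1988,6.7,29,11,1.9,1.4,15,1.8,1028,1.4
vegan,1.1,2353,349,54,78,0,78,869,2837,3333,5551,4538,2085,6006,3753,2004,78,0,667,3351,1336,17.2,1118,467,2460,8.0,34,12,2.0,0.9,16,2.0,1178,1.0
conventional,1.2,2079,286,25,84,58,26,959,3417,3960,6447,6302,3237,6340,4400,2415,67,906,969,2698,961,11.4,330,296,994,5.1,14,7,1.6,1.2,27,2.0,554,9.8
lacto_ovo,1.2,2290,313,38,85,25,60,1048,3232,3983,6786,5433,3005,7154,4684,2220,82,42,755,3087,1467,17.4,1442,401,1867,6.3,28,11,1.8,1.9,14,1.7,897,2.7
plado,1.2,2201,310,42,86,28,58,963,3279,3818,6267,5644,2698,6463,4241,2280,73,561,918,3245,1242,14.5,821,411,1882,6.2,27,10,1.9,1.0,23,2.2,922,7.1
ovo,1.2,2298,324,46,83,15,68,962,3128,3726,6166,4974,2645,6687,4346,2108,79,42,834,3119,1347,16.3,1064,429,2229,7.1,32,11,1.9,1.4,15,1.9,1062,2.3
lacto,1.2,2340,345,49,85,14,71,1012,3140,3839,6565,5370,2557,6882,4379,2267,75,0,590,3552,1554,18.3,1567,458,2212,7.3,33,12,2.0,1.4,16,1.9,1114,1.4
vegan,1.2,2410,366,58,84,0,84,936,3067,3609,6002,4962,2228,6483,4061,2179,74,0,672,3623,1452,17.3,1198,496,2640,8.5,37,13,2.1,1.0,17,2.1,1279,1.0
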