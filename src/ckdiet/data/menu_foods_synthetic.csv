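id,name,group,protein_source,exchange_grams,energy,protein,carbohydrate,fat,fiber,tryptophan,threonine,isoleucine,leucine,lysine,methionine,cysteine,phenylalanine_tyrosine,valine,histidine,epa_dha,sodium,potassium,phosphorus,calcium,magnesium,copper,manganese,iron,zinc,thiamine,riboflavin,niacin,pyridoxine,folate,cobalamin
white_rice,"White rice, cooked",cereal,none,55,131.8181818181818,3.6363636363636362,27.27272727272727,0.9090909090909091,1.0909090909090908,40.0,123.63636363636363,152.72727272727275,298.1818181818182,152.72727272727275,83.63636363636363,76.36363636363637,320.0,210.90909090909088,87.27272727272727,0.0,3.6363636363636362,63.63636363636363,63.63636363636363,9.090909090909092,21.818181818181817,72.72727272727273,0.7272727272727273,1.0909090909090908,0.7272727272727273,0.2181818181818182,0.03636363636363637,2.727272727272727,0.09090909090909091,105.45454545454544,0.0
dosa,Dosa (rice-lentil crepe),cereal,none,60,120.83333333333333,3.3333333333333335,25.0,0.8333333333333334,1.6666666666666667,36.666666666666664,113.33333333333333,140.0,273.3333333333333,140.0,76.66666666666667,70.0,293.3333333333333,193.33333333333334,80.0,0.0,100.0,100.0,75.0,13.333333333333334,23.333333333333332,91.66666666666666,0.5833333333333333,1.3333333333333335,0.8333333333333334,0.16666666666666669,0.06666666666666667,2.0,0.1,66.66666666666666,0.0
rice_noodles,"Rice noodles, cooked",cereal,none,57,127.19298245614034,3.508771929824561,26.31578947368421,0.8771929824561403,1.2280701754385965,38.59649122807017,119.29824561403508,147.36842105263156,287.719298245614,147.36842105263156,80.7017543859649,73.68421052631578,308.77192982456137,203.50877192982458,84.21052631578947,0.0,21.052631578947366,35.08771929824561,49.122807017543856,7.017543859649122,14.035087719298245,52.63157894736842,0.43859649122807015,0.7017543859649122,0.5263157894736842,0.03508771929824562,0.01754385964912281,0.8771929824561403,0.03508771929824562,10.526315789473683,0.0
marie_biscuit,Marie biscuit,cereal,none,25,326.0,8.0,60.0,6.0,2.0,88.0,272.0,336.0,656.0,336.0,184.0,168.0,704.0,463.99999999999994,192.0,0.0,280.0,120.0,120.0,40.0,24.0,100.0,0.6,2.0,0.8,0.2,0.12,2.4,0.08,48.0,0.0
papaya,Papaya,fruit,none,150,41.333333333333336,0.33333333333333337,10.0,0.0,1.7333333333333332,3.3333333333333335,12.0,12.666666666666668,21.333333333333336,16.666666666666664,4.666666666666667,4.0,20.0,14.666666666666666,6.666666666666667,0.0,0.0,180.0,0.0,20.0,20.666666666666668,46.666666666666664,0.039999999999999994,0.2666666666666667,0.06666666666666668,0.019999999999999997,0.02666666666666667,0.33333333333333337,0.039999999999999994,36.666666666666664,0.0
banana,Banana,fruit,none,65,95.38461538461539,0.7692307692307693,23.076923076923077,0.0,2.6153846153846154,7.6923076923076925,27.692307692307693,29.230769230769234,49.23076923076923,38.46153846153847,10.76923076923077,9.230769230769232,46.15384615384615,33.84615384615385,15.384615384615385,0.0,0.0,353.8461538461538,0.0,6.153846153846154,27.692307692307693,76.92307692307693,0.26153846153846155,0.3076923076923077,0.15384615384615385,0.03076923076923077,0.07692307692307693,0.6153846153846154,0.3692307692307692,20.0,0.0
pear,Pear,fruit,none,100,62.0,0.5,15.0,0.0,3.1,5.0,18.0,19.0,32.0,25.0,7.000000000000001,6.0,30.0,22.0,10.0,0.0,0.0,114.99999999999999,0.0,9.0,7.000000000000001,80.0,0.05,0.2,0.1,0.01,0.03,0.2,0.03,7.000000000000001,0.0
apple,Apple,fruit,none,110,56.36363636363636,0.45454545454545453,13.636363636363635,0.0,2.3636363636363638,4.545454545454546,16.363636363636363,17.272727272727273,29.09090909090909,22.727272727272727,6.363636363636363,5.454545454545454,27.27272727272727,20.0,9.090909090909092,0.0,0.0,109.09090909090908,0.0,6.363636363636363,5.454545454545454,27.27272727272727,0.03636363636363637,0.09090909090909091,0.045454545454545456,0.018181818181818184,0.027272727272727275,0.09090909090909091,0.045454545454545456,2.727272727272727,0.0
mango,Mango,fruit,none,100,62.0,0.5,15.0,0.0,1.6,5.0,18.0,19.0,32.0,25.0,7.000000000000001,6.0,30.0,22.0,10.0,0.0,0.0,170.0,0.0,11.0,10.0,110.00000000000001,0.06,0.2,0.1,0.03,0.04,0.7,0.12,43.0,0.0
orange,Orange,fruit,none,130,47.69230769230769,0.38461538461538464,11.538461538461538,0.0,2.3846153846153846,3.8461538461538463,13.846153846153847,14.615384615384617,24.615384615384617,19.230769230769234,5.384615384615385,4.615384615384616,23.076923076923077,16.923076923076923,7.6923076923076925,0.0,0.0,180.76923076923077,0.0,40.0,10.0,46.15384615384615,0.023076923076923075,0.07692307692307693,0.07692307692307693,0.08461538461538462,0.038461538461538464,0.3076923076923077,0.06153846153846154,30.0,0.0
okra,"Okra, cooked",vegetable,none,80,31.25,1.5625,6.25,0.0,2.5,18.75,62.5,65.625,109.375,87.5,25.0,18.75,112.5,75.0,34.375,0.0,6.25,137.5,32.5,77.5,36.25,87.5,0.3,0.25,0.375,0.13749999999999998,0.0625,0.8749999999999999,0.1875,46.25,0.0
cucumber,Cucumber,vegetable,none,90,27.77777777777778,1.3888888888888888,5.555555555555555,0.0,0.5555555555555556,16.666666666666664,55.55555555555556,58.333333333333336,97.22222222222221,77.77777777777779,22.22222222222222,16.666666666666664,100.0,66.66666666666666,30.555555555555557,0.0,2.2222222222222223,144.44444444444443,23.333333333333332,15.555555555555555,13.333333333333334,38.88888888888889,0.07777777777777778,0.2777777777777778,0.2222222222222222,0.022222222222222223,0.03333333333333333,0.1111111111111111,0.044444444444444446,6.666666666666667,0.0
eggplant,"Eggplant, cooked",vegetable,none,80,31.25,1.5625,6.25,0.0,2.5,18.75,62.5,65.625,109.375,87.5,25.0,18.75,112.5,75.0,34.375,0.0,2.5,125.0,15.0,6.25,11.25,56.25,0.11249999999999999,0.25,0.125,0.075,0.025,0.625,0.08750000000000001,13.750000000000002,0.0
cabbage,"Cabbage, cooked",vegetable,none,75,33.33333333333333,1.6666666666666667,6.666666666666667,0.0,1.8666666666666665,20.0,66.66666666666666,70.0,116.66666666666667,93.33333333333333,26.666666666666668,20.0,120.0,80.0,36.666666666666664,0.0,8.0,153.33333333333334,22.666666666666664,48.0,14.666666666666666,17.333333333333336,0.2,0.13333333333333336,0.2666666666666667,0.06666666666666668,0.039999999999999994,0.2666666666666667,0.10666666666666667,30.666666666666664,0.0
spinach,"Spinach, cooked",vegetable,none,90,27.77777777777778,1.3888888888888888,5.555555555555555,0.0,2.4444444444444446,16.666666666666664,55.55555555555556,58.333333333333336,97.22222222222221,77.77777777777779,22.22222222222222,16.666666666666664,100.0,66.66666666666666,30.555555555555557,0.0,70.0,466.6666666666667,50.0,135.55555555555557,86.66666666666667,172.22222222222223,0.9333333333333332,3.5555555555555554,0.7777777777777778,0.1,0.2333333333333333,0.4444444444444444,0.24444444444444444,145.55555555555554,0.0
vegetable_oil,Vegetable oil,fat,none,5,900.0,0.0,0.0,100.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
ghee,Ghee,fat,none,5,900.0,0.0,0.0,100.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
white_sugar,White sugar,sugar,none,15,400.0,0.0,100.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
black_tea,"Black tea, brewed",beverage,none,240,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,8.333333333333332,0.0,0.0,2.083333333333333,0.0,0.20833333333333334,0.0,0.0,0.0,0.0,0.0,0.0,5.0,0.0
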