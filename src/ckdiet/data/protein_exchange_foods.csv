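id,name,group,protein_source,exchange_grams,energy,protein,carbohydrate,fat,fiber,tryptophan,threonine,isoleucine,leucine,lysine,methionine,cysteine,phenylalanine_tyrosine,valine,histidine,epa_dha,sodium,potassium,phosphorus,calcium,magnesium,copper,manganese,iron,zinc,thiamine,riboflavin,niacin,pyridoxine,folate,cobalamin
king_mackerel,"King mackerel, cooked",protein_food,animal_fish,35,195.7142857142857,20.0,0.0,12.857142857142856,0.0,222.85714285714286,942.8571428571429,971.4285714285713,1648.5714285714284,1862.857142857143,600.0,217.14285714285714,1571.4285714285713,1114.2857142857142,942.8571428571429,857.1428571428571,71.42857142857143,342.85714285714283,228.57142857142856,17.142857142857142,34.285714285714285,57.14285714285714,0.028571428571428574,1.7142857142857144,0.8571428571428572,0.08571428571428572,0.34285714285714286,8.571428571428571,0.4285714285714286,8.571428571428571,15.714285714285714
chicken,"Chicken, cooked",protein_food,animal_poultry,30,183.33333333333331,23.333333333333332,0.0,10.0,0.0,266.66666666666663,1000.0,1200.0,1733.3333333333333,1963.3333333333333,640.0,296.6666666666667,1733.3333333333333,1166.6666666666665,716.6666666666667,26.666666666666668,66.66666666666666,233.33333333333334,183.33333333333331,13.333333333333334,26.666666666666668,50.0,0.016666666666666666,1.0,1.0,0.06666666666666667,0.16666666666666669,9.333333333333332,0.4,6.666666666666667,0.33333333333333337
egg,"Egg, whole, boiled",protein_food,animal_egg,56,138.03571428571428,12.5,0.7142857142857143,9.464285714285714,0.0,160.71428571428572,553.5714285714286,660.7142857142857,1087.5,914.2857142857142,380.35714285714283,271.42857142857144,1035.7142857142858,767.8571428571429,303.57142857142856,37.5,139.28571428571428,137.5,192.85714285714286,55.35714285714286,12.5,71.42857142857143,0.026785714285714288,1.7857142857142856,1.25,0.03571428571428571,0.4464285714285714,0.07142857142857142,0.1607142857142857,46.42857142857143,0.8928571428571428
whole_milk,Whole milk,protein_food,animal_dairy,220,61.45454545454545,3.1818181818181817,4.818181818181818,3.272727272727273,0.0,45.45454545454545,127.27272727272727,172.72727272727272,265.0,140.0,75.0,16.818181818181817,295.45454545454544,204.54545454545453,86.36363636363636,0.0,43.18181818181818,131.8181818181818,84.0909090909091,113.63636363636364,10.0,25.0,0.003181818181818182,0.03181818181818182,0.36363636363636365,0.045454545454545456,0.16818181818181818,0.09090909090909091,0.03636363636363637,5.0,0.45454545454545453
tofu,"Tofu, firm",protein_food,plant_soy,87,82.98850574712644,8.045977011494253,1.839080459770115,4.827586206896552,0.9195402298850575,126.4367816091954,333.33333333333337,402.2988505747127,613.7931034482759,532.183908045977,103.44827586206897,111.49425287356323,643.6781609195402,413.7931034482759,229.88505747126436,0.0,13.793103448275861,160.91954022988506,126.4367816091954,344.8275862068965,36.7816091954023,195.4022988505747,0.6321839080459771,1.6091954022988506,0.8045977011494253,0.08045977011494254,0.05747126436781609,0.22988505747126436,0.04597701149425287,19.54022988505747,0.0
lentils,"Lentils (dhal), cooked",protein_food,plant_legume,78,119.87179487179486,8.974358974358974,20.128205128205128,0.3846153846153846,7.94871794871795,89.74358974358975,358.974358974359,435.89743589743586,653.8461538461538,629.4871794871794,76.92307692307693,117.94871794871796,769.2307692307693,500.0,282.05128205128204,0.0,2.564102564102564,365.38461538461536,179.4871794871795,19.230769230769234,35.8974358974359,250.0,0.4871794871794872,3.3333333333333335,1.282051282051282,0.16666666666666669,0.07692307692307693,1.0256410256410255,0.17948717948717952,179.4871794871795,0.0
chickpeas,"Chickpeas, cooked",protein_food,plant_legume,80,167.625,8.75,27.250000000000004,2.6250000000000004,7.625,93.75,337.5,412.5,631.25,592.5,116.25000000000001,118.75,737.5,425.0,268.75,0.0,7.5,287.5,168.75,50.0,47.5,350.0,1.0499999999999998,2.875,1.5,0.11249999999999999,0.0625,0.5,0.13749999999999998,171.25,0.0
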