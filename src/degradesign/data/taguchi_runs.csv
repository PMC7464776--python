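run,ph,temperature_k,methanol_mg_l,acetic_acid_mg_l,h2o2_mg_l,voltage_v_m,surfactant_mg_l,binding_free_energy_kj_mol
1,6.5,298,400,200,300,0.5,0,−88.461
2,6.5,298,400,200,350,1,375,−77.231
3,6.5,298,400,200,400,1.5,750,−76.508
4,6.5,303,450,300,300,0.5,0,−75.584
5,6.5,303,450,300,350,1,375,−84.364
6,6.5,303,450,300,400,1.5,750,−90.252
7,6.5,308,500,400,300,0.5,0,−90.39
8,6.5,308,500,400,350,1,375,−75.769
9,6.5,308,500,400,400,1.5,750,−82.256
10,7.5,298,450,400,300,1,750,−80.197
11,7.5,298,450,400,350,1.5,0,−69.418
12,7.5,298,450,400,400,0.5,375,−70.905
13,7.5,303,500,200,300,1,750,−103.79
14,7.5,303,500,200,350,1.5,0,−84.974
15,7.5,303,500,200,400,0.5,375,−65.508
16,7.5,308,400,300,300,1,750,−82.256
17,7.5,308,400,300,350,1.5,0,−60.265
18,7.5,308,400,300,400,0.5,375,−58.644
19,8.5,298,500,300,300,1.5,375,−78.007
20,8.5,298,500,300,350,0.5,750,−62.709
21,8.5,298,500,300,400,1,0,−87.278
22,8.5,303,400,400,300,1.5,375,−74.697
23,8.5,303,400,400,350,0.5,750,−67.101
24,8.5,303,400,400,400,1,0,−85.287
25,8.5,308,450,200,300,1.5,375,−88.545
26,8.5,308,450,200,350,0.5,750,−62.199
27,8.5,308,450,200,400,1,0,−55.286
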