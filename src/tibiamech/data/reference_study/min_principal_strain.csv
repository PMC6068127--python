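region,non_normal,all_mean,all_sd,cv_rms,oa_central,oa_sd,normal_central,normal_sd,difference_absolute,difference_percent,ci_low,ci_high,p_value,cohens_d
Medial peripheral cortical,0,1185,512,6.1,1135,561,1236,497,-101,-8.2,-719,516,0.727,0.2
Medial epiphyseal cortical,0,1410,601,4.2,1435,666,1385,582,50,3.6,-678,778,0.883,0.08
Medial metaphyseal cortical,0,1130,418,4.7,1247,433,1014,399,233,23.0,-252,718,0.316,0.56
Medial subchondral cortical,1,563,203,5.6,536,258,512,143,16,3.1,-164,258,0.949,0.28
Medial subchondral trabecular,1,770,322,6.5,743,405,627,189,118,18.8,-155,636,0.338,0.64
Medial epiphyseal trabecular,1,2405,900,3.7,2294,1133,1990,599,281,14.1,-557,1403,0.406,0.49
Medial metaphyseal trabecular,0,2166,933,4.7,2361,1096,1970,771,391,19.8,-712,1494,0.455,0.42
Subchondral spine,1,830,403,7.2,749,544,725,186,27,3.7,-282,817,0.848,0.48
Epiphyseal central,0,2688,879,3.2,2873,1015,2503,752,370,14.8,-670,1410,0.454,0.42
Metaphyseal central,0,1897,789,4.9,2053,921,1741,668,312,17.9,-625,1248,0.482,0.39
Lateral subchondral cortical,0,862,330,6.4,914,410,809,249,106,13.1,-289,500,0.571,0.32
Lateral subchondral trabecular,0,1321,447,5.2,1495,548,1148,249,347,30.2,-149,843,0.154,0.78
Lateral epiphyseal trabecular,1,2508,860,3.9,2434,1006,1979,611,559,28.2,-346,1735,0.18,0.71
Lateral metaphyseal trabecular,0,1940,829,7.5,2080,948,1800,738,280,15.6,-709,1269,0.549,0.34
Lateral peripheral cortical,1,1157,492,5.7,933,657,964,236,10,1.0,-194,953,0.848,0.5
Lateral epiphyseal cortical,0,1105,403,5.9,1181,475,1030,337,151,14.7,-329,631,0.506,0.37
Lateral metaphyseal cortical,0,670,288,7.4,656,274,685,323,-30,-4.3,-378,319,0.857,0.1
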