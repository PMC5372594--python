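protease,no,retention_time_min,apparent_mass_da,reported_theoretical_mass_da,reported_span
trypsin,1,11.910,1024.4663,1024.4694,28-39
trypsin,2,13.936,991.4494,991.4513,13-20
trypsin,3,18.260,1278.5927,1278.5960,1-12
trypsin,4,33.747,948.5579,948.5553,21-27
chymotrypsin,5,12.570,1265.6440,1265.6484,26-39
chymotrypsin,6,13.420,647.2809,647.2784,1-6
chymotrypsin,7,24.620,447.2233,447.2238,23-25
chymotrypsin,8,27.026,1735.8964,1735.8531,7-21
chymotrypsin,9,29.595,594.2947,594.2922,22-25
chymotrypsin,10,30.445,2364.1284,2364.1137,1-21
chymotrypsin,11,33.593,1882.9354,1882.9216,7-22
chymotrypsin,12,35.891,2511.1896,2511.1822,1-22
elastase,13,7.424,288.2029,288.2029,20-21
elastase,14,26.439,2094.9582,2094.9286,1-19
elastase,15,26.982,1841.0082,1840.9228,22-39
elastase,16,30.438,2364.1284,2364.1137,1-21
elastase,17,34.816,707.3790,707.3763,22-26
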