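region,population,building_function,n_tested,mean_rn,sd,range_low,range_high
Prince George,74003,home,1436,185,,,1550
Prince George,74003,school,44,30,,,240
Prince George,74003,public,10,38,,,150
Prince George,74003,public,14,25,40,,148
Castlegar,8039,home,158,373,,50,1250
Castlegar,8039,school,13,100,,,855
Okanagan region,362258,home,217,137,163,,1410
Okanagan region,362258,school,131,44,,,400
Okanagan region,362258,public,59,40,51,,276
Calgary,1392609,home,2382,126,,15,3440
Calgary,1392609,home,185,111,92,,850
Calgary,1392609,public,27,43,,,288
Calgary,1392609,public,20,19,12,,106
Edmonton,1321426,home,170,101,62,,386
Edmonton,1321426,public,10,24,,,58
Edmonton,1321426,public,119,19,14,,169
Ottawa,934243,home,266,99,116,,1525
Ottawa,934243,public,255,30,41,,408
Gaspesie region,90311,home,174,158,270,,2923
Gaspesie region,90311,school,19,76,116,15,663
Gaspesie region,90311,public,40,122,251,,1580
Laurentides region,589400,home,78,88,124,,757
Laurentides region,589400,school,22,57,65,15,453
Outaouais region,382604,home,62,111,170,,917
Outaouais region,382604,school,24,44,37,15,206
Saskatchewan,1098352,home,1604,153,132,,2165
Saskatchewan,1098352,school,424,73,91,11,1243
Saskatchewan,1098352,public,56,47,32,,120
Saskatchewan,1098352,public,342,71,91,,530
Nova Scotia,923598,home,758,130,247,,2690
Nova Scotia,923598,school,377,62,46,,1312
Nova Scotia,923598,public,20,27,,,200
Nova Scotia,923598,public,581,38,69,,870
Prince Edward Island,142907,home,113,46,67,,415
Prince Edward Island,142907,senior_housing,38,43,37,11,169
Prince Edward Island,142907,school,46,68,58,10,305
Prince Edward Island,142907,public,8,34,46,12,146
Prince Edward Island,142907,public,51,25,31,,204
Yukon,35874,home,225,175,309,,2360
Yukon,35874,school,32,65,58,6,430
Yukon,35874,public,56,58,53,,290
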