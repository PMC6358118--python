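region,private_2010_2012,government_2010_2012,dev_flows_2013_2014,oda_climate_2013_2014,multilateral_climate_2013_2014
Africa,10027,3104,3163,1443,97
Northern Africa,1941,1140,59,15,0
South of the Sahara,8086,1964,3104,1428,97
Eastern Africa,2306,591,1267,652,42
Central Africa,388,138,29,7,3
Southern Africa,1553,479,45,23,3
Western Africa,3838,756,1114,369,47
Other Developing Countries,142635,71286,5057,2034,227
Developing Countries,152662,74390,8219,3477,324
Developed Countries,155969,54082,–,–,–
World,308631,128472,8219,3477,324
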