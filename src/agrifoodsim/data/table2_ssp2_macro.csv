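region,pop_2010,pop_2020,pop_2030,gdp_2010,gdp_2020,gdp_2030,income_2010,income_2020,income_2030
Africa,1032,1279,1538,2.8,4.5,7.7,2.7,3.6,5.0
Northern Africa,223,260,293,1.2,1.8,2.9,5.2,6.9,9.9
South of the Sahara,863,1086,1326,1.7,2.9,5.0,2.0,2.7,3.8
Western Africa,304,386,479,0.5,1.0,1.9,1.7,2.5,3.9
Eastern Africa,321,407,498,0.3,0.6,1.1,1.0,1.5,2.3
Central Africa,127,162,200,0.2,0.4,0.6,1.9,2.4,3.1
Southern Africa,58,63,68,0.5,0.8,1.1,9.0,12.3,16.6
Other Developing Countries,4508,4903,5205,26.6,48.4,76.1,5.9,9.9,14.6
Developing Countries,5778,6460,7058,31.4,56.0,88.2,5.4,8.7,12.5
Developed Countries,1102,1167,1222,36.1,45.3,55.0,32.8,38.8,45.0
World,6879,7626,8280,67.6,101.3,143.1,9.8,13.3,17.3
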