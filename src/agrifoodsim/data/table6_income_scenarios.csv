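region,income_2010,nocc_2030,cc_2030,comp_2030
Africa,2.7,5.0,4.9,5.1
Northern Africa,5.2,9.9,9.8,10.2
South of Sahara,1.9,3.8,3.8,4.0
Western Africa,1.7,3.9,3.8,4.1
Eastern Africa,1.0,2.3,2.3,2.3
Central Africa,1.9,3.1,3.1,3.2
Southern Africa,9.0,16.6,16.5,17.3
Developing Countries,5.4,12.5,12.4,12.9
World,9.8,17.3,17.2,17.6
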