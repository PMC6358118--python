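region,irrigated_area,water_use_efficiency,soil_water_availability
Africa South of the Sahara,30,30,15
North Africa and West Asia,5,25,5
Africa and West Asia,13,27,14
Other Developing Countries,5,25,6
All Developing Countries,6,25,8
World,5,20,6
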