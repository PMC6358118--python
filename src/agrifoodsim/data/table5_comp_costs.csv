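region,agricultural_rnd,irrigation_expansion,water_use_efficiency,soil_water_management,infrastructure,total
Africa South of the Sahara,0.67,2.76,0.41,1.76,4.52,10.1
North Africa and West Asia,0.01,0.83,0.61,1.28,2.06,4.8
Africa and West Asia,0.67,3.59,1.02,3.04,6.57,14.9
Other Developing Countries,0.07,4.34,9.25,4.19,19.36,37.2
All Developing Countries,0.74,7.93,10.27,7.23,25.94,52.1
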