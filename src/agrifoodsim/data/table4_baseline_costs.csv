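region,cgiar,nars,irrigated_area,water_use,soil_management,infrastructure,total
Africa South of the Sahara,0.68,0.85,2.98,0.13,0.88,0.17,5.7
North Africa and West Asia,0.06,1.12,0.81,0.07,0.64,0.90,3.6
Africa and West Asia,0.74,1.97,3.79,0.20,1.52,1.07,9.3
Other Developing Countries,0.41,3.38,3.77,2.02,2.10,24.50,36.2
All Developing Countries,1.16,5.35,7.56,2.22,3.62,25.57,45.5
Developed Countries,–,13.26,0.56,0.17,–,26.92,40.9
World,1.16,18.61,8.12,2.39,3.62,52.49,86.4
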