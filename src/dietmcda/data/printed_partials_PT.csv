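scenario,profitability,affordability,local_econ_dev,local_communities,acceptance,fair_practices,accessibility,diet_health,env_health,biodiversity,climate_change,water_use,land_use,pollution
0%,0,0,66.7,0,100,0,0,0,10,-2.27,-37.04,85.15,46.67,5
25%,33,140,-66.67,100,0,127.27,0,5.9,45,13.84,0,88.3,80,37.5
50%,66,223.33,-66.67,100,-233.33,127.27,0,11.1,80,29.48,66.67,91.13,113.33,65
75%,99,286.67,-66.67,0,-233.33,127.27,0,15.9,115,48.33,111.11,94.45,146.67,90
100%,132,346.67,-66.67,0,-233.33,127.27,0,20,145,70.67,133.33,97.45,180,135
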