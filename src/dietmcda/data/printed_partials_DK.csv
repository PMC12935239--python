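scenario,profitability,affordability,local_econ_dev,local_communities,acceptance,fair_practices,accessibility,diet_health,env_health,biodiversity,climate_change,water_use,land_use,pollution
0%,0,0,-66.7,0,100,0,,0,10,-93.6,-111.1,64.8,133.3,25
25%,-19.8,160,-66.7,100,0,127.3,,10.7,45,-54.5,-55.6,70.8,140,47.5
50%,-39.5,246.7,-66.7,100,-233,127.3,,20.8,80,-9.5,0,76.8,153.3,70
75%,-60.8,323.3,-66.7,0,-233,127.3,,30.5,115,24.4,66.7,82.9,166.7,92.5
100%,-83.8,396.7,-66.7,0,-233,127.3,,39.7,145,61.3,122.2,88.9,173.3,125
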