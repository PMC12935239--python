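scenario,profitability,affordability,local_econ_dev,local_communities,acceptance,fair_practices,accessibility,diet_health,env_health,biodiversity,climate_change,water_use,land_use,pollution
0%,0,0,L6,L4,L1,L5,,0,0.28,54.4,1.2,33.5,1,4
25%,-7.90,22,L6,L1,L2,L1,,-10.7,0.21,42.4,0.9,29.5,0.9,3.1
50%,-15.79,44.01,L6,L1,L4,L1,,-20.8,0.14,30.5,0.6,25.5,0.7,2.2
75%,-23.69,66.99,L6,L4,L4,L1,,-30.5,0.07,18.5,0.4,21.4,0.5,1.3
100%,-31.59,89.01,L6,L4,L4,L1,,-39.7,0.01,6.6,0.1,17.4,0.4,0.5
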