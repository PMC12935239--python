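scenario,profitability,affordability,local_econ_dev,local_communities,acceptance,fair_practices,accessibility,diet_health,env_health,biodiversity,climate_change,water_use,land_use,pollution
0%,0,0,L2,L4,L1,L5,L2,0,0.28,28.6,0.8,19.9,2.3,4.5
25%,13.21,18,L6,L1,L2,L1,L2,-5.9,0.21,22.6,0.6,17.8,1.8,3.5
50%,26.42,37,L6,L1,L4,L1,L2,-11.1,0.14,16.5,0.4,15.8,1.3,2.4
75%,39.63,56,L6,L4,L4,L1,L2,-15.8,0.07,10.5,0.2,13.7,0.8,1.4
100%,52.84,74,L6,L4,L4,L1,L2,-20,0.01,4.4,0,11.7,0.3,0.3
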