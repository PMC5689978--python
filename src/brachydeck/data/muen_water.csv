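energy_mev,muen_over_rho
0.010,4.944
0.015,1.374
0.020,0.5503
0.030,0.1557
0.040,0.06947
0.050,0.04223
0.060,0.0319
0.080,0.02597
0.100,0.02546
0.150,0.02764
0.200,0.02967
0.300,0.03192
0.400,0.03279
0.500,0.03299
0.600,0.03284
0.800,0.03206
1.000,0.03103
1.250,0.02965
1.500,0.02833
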