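energy_mev,intensity
0.136343,0.00199
0.201311,0.00473
0.205794,0.0334
0.283267,0.00266
0.295957,0.2871
0.308455,0.297
0.316506,0.8286
0.374485,0.00726
0.416469,0.0067
0.468069,0.4781
0.484575,0.03189
0.489060,0.00438
0.588581,0.04517
0.604411,0.082
0.612462,0.0534
0.884537,0.00292
1.061480,0.00053
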