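hu,density
-1000,0.0012
-700,0.3
0,1.0
300,1.2
1200,1.85
3000,2.7
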