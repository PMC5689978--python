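r_cm,g
0.1,0.989065
0.15,0.989821
0.2,0.990560
0.25,0.991281
0.3,0.991985
0.4,0.993340
0.5,0.994625
0.6,0.995840
0.8,0.998060
1,1.000000
1.25,1.002031
1.5,1.003625
1.75,1.004781
2,1.005500
2.5,1.005625
3,1.004000
3.5,1.000625
4,0.995500
4.5,0.988625
5,0.980000
6,0.957500
7,0.928000
8,0.891500
10,0.797500
12,0.675500
15,0.440000
18,0.141500
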