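low,high,representative
0.0012,0.05,0.0012
0.05,0.082,0.05
0.082,0.114,0.082
0.114,0.146,0.12
0.146,0.178,0.15
0.178,0.21,0.18
0.21,0.242,0.21
0.242,0.274,0.25
0.274,0.306,0.28
0.306,0.338,0.31
0.338,0.37,0.34
0.37,0.402,0.37
0.402,0.434,0.41
0.434,0.466,0.44
0.466,0.498,0.47
0.498,0.53,0.5
0.53,0.562,0.53
0.562,0.594,0.57
0.594,0.626,0.6
0.626,0.658,0.63
0.658,0.69,0.66
0.69,0.722,0.69
0.722,0.754,0.73
0.754,0.786,0.76
0.786,0.818,0.79
0.818,0.85,0.82
0.85,0.87,0.85
0.87,0.89,0.87
0.89,0.91,0.89
0.91,0.93,0.91
0.93,0.95,0.93
0.95,0.97,0.95
0.97,0.99,0.97
0.99,1.01,1
1.01,1.11,1.1
1.11,1.21,1.2
1.21,1.31,1.3
1.31,1.41,1.4
1.41,1.51,1.5
1.51,1.61,1.6
1.61,1.71,1.7
1.71,1.81,1.8
1.81,1.91,1.9
1.91,2.01,2
2.01,2.11,2.1
2.11,2.21,2.2
2.21,2.31,2.3
2.31,2.41,2.4
2.41,2.51,2.5
2.51,2.61,2.6
2.61,2.71,2.7
2.71,2.81,2.8
2.81,2.91,2.9
2.91,3,3
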