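name,low,high,H,C,N,O,Na,Mg,P,S,Cl,Ar,K,Ca
air,0,0.05,0.000000,0.000124,0.755268,0.231781,0.000000,0.000000,0.000000,0.000000,0.000000,0.012827,0.000000,0.000000
lung,0.05,0.6,0.103000,0.105000,0.031000,0.749000,0.002000,0.000000,0.002000,0.003000,0.003000,0.000000,0.002000,0.000000
adipose,0.6,0.93,0.114000,0.598000,0.007000,0.278000,0.001000,0.000000,0.000000,0.001000,0.001000,0.000000,0.000000,0.000000
breast,0.93,0.97,0.109000,0.506000,0.023000,0.358000,0.001000,0.000000,0.001000,0.001000,0.001000,0.000000,0.000000,0.000000
soft_tissue,0.97,1.01,0.112000,0.000000,0.000000,0.888000,0.000000,0.000000,0.000000,0.000000,0.000000,0.000000,0.000000,0.000000
muscle,1.01,1.04,0.102000,0.143000,0.034000,0.710000,0.001000,0.000000,0.002000,0.003000,0.001000,0.000000,0.004000,0.000000
liver,1.04,1.06,0.102000,0.139000,0.030000,0.716000,0.002000,0.000000,0.003000,0.003000,0.002000,0.000000,0.003000,0.000000
cartilage,1.06,1.1,0.096000,0.099000,0.022000,0.744000,0.005000,0.000000,0.022000,0.009000,0.003000,0.000000,0.000000,0.000000
skeletal_d1.125,1.1,1.15,0.083445,0.396409,0.057512,0.369073,0.001000,0.001030,0.036104,0.002030,0.001939,0.000000,0.000970,0.050488
skeletal_d1.175,1.15,1.2,0.080335,0.381226,0.056537,0.373220,0.001000,0.001091,0.040311,0.002091,0.001817,0.000000,0.000909,0.061463
skeletal_d1.225,1.2,1.25,0.077226,0.366043,0.055561,0.377366,0.001000,0.001152,0.044518,0.002152,0.001695,0.000000,0.000848,0.072439
skeletal_d1.275,1.25,1.3,0.074116,0.350860,0.054585,0.381512,0.001000,0.001213,0.048726,0.002213,0.001573,0.000000,0.000787,0.083415
skeletal_d1.325,1.3,1.35,0.071006,0.335677,0.053610,0.385659,0.001000,0.001274,0.052933,0.002274,0.001451,0.000000,0.000726,0.094390
skeletal_d1.375,1.35,1.4,0.067896,0.320494,0.052634,0.389806,0.001000,0.001335,0.057140,0.002335,0.001329,0.000000,0.000665,0.105366
skeletal_d1.425,1.4,1.45,0.064787,0.305311,0.051659,0.393951,0.001000,0.001396,0.061348,0.002396,0.001207,0.000000,0.000604,0.116341
skeletal_d1.475,1.45,1.5,0.061677,0.290128,0.050683,0.398098,0.001000,0.001457,0.065555,0.002457,0.001085,0.000000,0.000543,0.127317
skeletal_d1.525,1.5,1.55,0.058567,0.274945,0.049707,0.402245,0.001000,0.001518,0.069762,0.002518,0.000963,0.000000,0.000482,0.138293
skeletal_d1.575,1.55,1.6,0.055457,0.259762,0.048732,0.406391,0.001000,0.001579,0.073970,0.002579,0.000841,0.000000,0.000421,0.149268
skeletal_d1.625,1.6,1.65,0.052348,0.244579,0.047756,0.410536,0.001000,0.001640,0.078177,0.002640,0.000720,0.000000,0.000360,0.160244
skeletal_d1.675,1.65,1.7,0.049238,0.229396,0.046780,0.414683,0.001000,0.001701,0.082384,0.002701,0.000598,0.000000,0.000299,0.171220
skeletal_d1.725,1.7,1.75,0.046128,0.214213,0.045805,0.418830,0.001000,0.001762,0.086591,0.002762,0.000476,0.000000,0.000238,0.182195
dense_bone,1.75,2,0.046750,0.217250,0.046000,0.418000,0.001000,0.001750,0.085750,0.002750,0.000500,0.000000,0.000250,0.180000
cortical_bone,2,3,0.034000,0.155000,0.042000,0.435000,0.001000,0.002000,0.103000,0.003000,0.000000,0.000000,0.000000,0.225000
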