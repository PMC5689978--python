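r_cm\theta_deg,0,5,10,15,20,25,30,35,40,45,50,55,60,65,70,75,80,85,90,95,100,105,110,115,120,125,130,135,140,145,150,155,160,165,170,175,180
0.25,0.877726,0.878886,0.882317,0.887877,0.895336,0.904385,0.914658,0.925742,0.937199,0.948590,0.959496,0.969534,0.978385,0.985803,0.991635,0.995833,0.998464,0.999726,1.000000,0.999726,0.998464,0.995833,0.991635,0.985803,0.978385,0.969534,0.959496,0.948590,0.937199,0.925742,0.914658,0.904385,0.895336,0.887877,0.882317,0.878886,0.877726
0.5,0.863863,0.865154,0.868975,0.875165,0.883469,0.893545,0.904983,0.917322,0.930078,0.942761,0.954903,0.966080,0.975934,0.984193,0.990687,0.995361,0.998289,0.999695,1.000000,0.999695,0.998289,0.995361,0.990687,0.984193,0.975934,0.966080,0.954903,0.942761,0.930078,0.917322,0.904983,0.893545,0.883469,0.875165,0.868975,0.865154,0.863863
1,0.850000,0.851423,0.855632,0.862453,0.871603,0.882705,0.895307,0.908903,0.922958,0.936933,0.950311,0.962626,0.973483,0.982583,0.989738,0.994888,0.998115,0.999664,1.000000,0.999664,0.998115,0.994888,0.989738,0.982583,0.973483,0.962626,0.950311,0.936933,0.922958,0.908903,0.895307,0.882705,0.871603,0.862453,0.855632,0.851423,0.850000
2,0.836137,0.837691,0.842290,0.849741,0.859736,0.871864,0.885631,0.900484,0.915838,0.931104,0.945719,0.959172,0.971033,0.980974,0.988790,0.994416,0.997941,0.999633,1.000000,0.999633,0.997941,0.994416,0.988790,0.980974,0.971033,0.959172,0.945719,0.931104,0.915838,0.900484,0.885631,0.871864,0.859736,0.849741,0.842290,0.837691,0.836137
3,0.828028,0.829659,0.834485,0.842305,0.852795,0.865523,0.879971,0.895559,0.911673,0.927695,0.943033,0.957151,0.969599,0.980032,0.988235,0.994139,0.997839,0.999614,1.000000,0.999614,0.997839,0.994139,0.988235,0.980032,0.969599,0.957151,0.943033,0.927695,0.911673,0.895559,0.879971,0.865523,0.852795,0.842305,0.834485,0.829659,0.828028
4,0.822274,0.823960,0.828948,0.837029,0.847870,0.861024,0.875956,0.892065,0.908718,0.925275,0.941127,0.955718,0.968582,0.979364,0.987842,0.993943,0.997767,0.999601,1.000000,0.999601,0.997767,0.993943,0.987842,0.979364,0.968582,0.955718,0.941127,0.925275,0.908718,0.892065,0.875956,0.861024,0.847870,0.837029,0.828948,0.823960,0.822274
5,0.817811,0.819540,0.824652,0.832937,0.844050,0.857534,0.872841,0.889355,0.906426,0.923399,0.939648,0.954606,0.967793,0.978846,0.987536,0.993791,0.997711,0.999591,1.000000,0.999591,0.997711,0.993791,0.987536,0.978846,0.967793,0.954606,0.939648,0.923399,0.906426,0.889355,0.872841,0.857534,0.844050,0.832937,0.824652,0.819540,0.817811
7,0.811082,0.812874,0.818175,0.826766,0.838289,0.852272,0.868144,0.885268,0.902969,0.920570,0.937419,0.952929,0.966604,0.978065,0.987076,0.993562,0.997626,0.999576,1.000000,0.999576,0.997626,0.993562,0.987076,0.978065,0.966604,0.952929,0.937419,0.920570,0.902969,0.885268,0.868144,0.852272,0.838289,0.826766,0.818175,0.812874,0.811082
10,0.803948,0.805808,0.811310,0.820225,0.832183,0.846694,0.863165,0.880936,0.899306,0.917570,0.935056,0.951152,0.965343,0.977236,0.986588,0.993319,0.997537,0.999560,1.000000,0.999560,0.997537,0.993319,0.986588,0.977236,0.965343,0.951152,0.935056,0.917570,0.899306,0.880936,0.863165,0.846694,0.832183,0.820225,0.811310,0.805808,0.803948
15,0.795839,0.797776,0.803505,0.812789,0.825242,0.840353,0.857505,0.876011,0.895141,0.914161,0.932370,0.949131,0.963909,0.976295,0.986033,0.993042,0.997435,0.999542,1.000000,0.999542,0.997435,0.993042,0.986033,0.976295,0.963909,0.949131,0.932370,0.914161,0.895141,0.876011,0.857505,0.840353,0.825242,0.812789,0.803505,0.797776,0.795839
18,0.792193,0.794164,0.799996,0.809445,0.822121,0.837501,0.854960,0.873796,0.893268,0.912628,0.931162,0.948223,0.963264,0.975871,0.985784,0.992918,0.997389,0.999534,1.000000,0.999534,0.997389,0.992918,0.985784,0.975871,0.963264,0.948223,0.931162,0.912628,0.893268,0.873796,0.854960,0.837501,0.822121,0.809445,0.799996,0.794164,0.792193
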