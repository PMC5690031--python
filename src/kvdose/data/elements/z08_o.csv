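# element O Z=8 A=15.999
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,4.67881e+01,6.56315e-01,1.96500e-01,4.67562e+01
6,2.66622e+01,5.17437e-01,1.95758e-01,2.66484e+01
7,1.65303e+01,4.14564e-01,1.95023e-01,1.65244e+01
8,1.09047e+01,3.38074e-01,1.94296e-01,1.09027e+01
9,7.54422e+00,2.80356e-01,1.93576e-01,7.54448e+00
10,5.41984e+00,2.35986e-01,1.92862e-01,5.42151e+00
11,4.01466e+00,2.01234e-01,1.92156e-01,4.01730e+00
12,3.05013e+00,1.73537e-01,1.91456e-01,3.05349e+00
13,2.36733e+00,1.51118e-01,1.90763e-01,2.37127e+00
14,1.87117e+00,1.32723e-01,1.90077e-01,1.87560e+00
15,1.50247e+00,1.17448e-01,1.89397e-01,1.50734e+00
16,1.22312e+00,1.04628e-01,1.88723e-01,1.22837e+00
17,1.00782e+00,9.37680e-02,1.88056e-01,1.01344e+00
18,8.39390e-01,8.44900e-02,1.87395e-01,8.45350e-01
19,7.05844e-01,7.65038e-02,1.86741e-01,7.12131e-01
20,5.98686e-01,6.95824e-02,1.86092e-01,6.05286e-01
21,5.11769e-01,6.35462e-02,1.85449e-01,5.18673e-01
22,4.40578e-01,5.82520e-02,1.84812e-01,4.47778e-01
23,3.81749e-01,5.35840e-02,1.84181e-01,3.89236e-01
24,3.32738e-01,4.94484e-02,1.83556e-01,3.40506e-01
25,2.91602e-01,4.57678e-02,1.82937e-01,2.99645e-01
26,2.56838e-01,4.24785e-02,1.82323e-01,2.65151e-01
27,2.27272e-01,3.95275e-02,1.81714e-01,2.35849e-01
28,2.01980e-01,3.68703e-02,1.81111e-01,2.10817e-01
29,1.80224e-01,3.44696e-02,1.80513e-01,1.89317e-01
30,1.61416e-01,3.22936e-02,1.79921e-01,1.70759e-01
31,1.45078e-01,3.03154e-02,1.79334e-01,1.54669e-01
32,1.30824e-01,2.85119e-02,1.78752e-01,1.40657e-01
33,1.18334e-01,2.68633e-02,1.78175e-01,1.28407e-01
34,1.07349e-01,2.53525e-02,1.77603e-01,1.17657e-01
35,9.76503e-02,2.39647e-02,1.77036e-01,1.08191e-01
36,8.90582e-02,2.26870e-02,1.76474e-01,9.98271e-02
37,8.14213e-02,2.15080e-02,1.75916e-01,9.24153e-02
38,7.46121e-02,2.04181e-02,1.75364e-01,8.58280e-02
39,6.85230e-02,1.94084e-02,1.74816e-01,7.99575e-02
40,6.30626e-02,1.84714e-02,1.74273e-01,7.47126e-02
41,5.81529e-02,1.76003e-02,1.73734e-01,7.00152e-02
42,5.37272e-02,1.67892e-02,1.73200e-01,6.57988e-02
43,4.97280e-02,1.60326e-02,1.72671e-01,6.20061e-02
44,4.61061e-02,1.53258e-02,1.72146e-01,5.85876e-02
45,4.28185e-02,1.46647e-02,1.71625e-01,5.55006e-02
46,3.98281e-02,1.40453e-02,1.71108e-01,5.27080e-02
47,3.71025e-02,1.34643e-02,1.70596e-01,5.01775e-02
48,3.46136e-02,1.29186e-02,1.70088e-01,4.78810e-02
49,3.23365e-02,1.24054e-02,1.69584e-01,4.57936e-02
50,3.02496e-02,1.19222e-02,1.69084e-01,4.38938e-02
51,2.83336e-02,1.14667e-02,1.68588e-01,4.21624e-02
52,2.65717e-02,1.10369e-02,1.68097e-01,4.05826e-02
53,2.49490e-02,1.06308e-02,1.67609e-01,3.91395e-02
54,2.34522e-02,1.02468e-02,1.67125e-01,3.78199e-02
55,2.20695e-02,9.88330e-03,1.66645e-01,3.66120e-02
56,2.07903e-02,9.53886e-03,1.66168e-01,3.55053e-02
57,1.96054e-02,9.21217e-03,1.65696e-01,3.44906e-02
58,1.85064e-02,8.90203e-03,1.65227e-01,3.35595e-02
59,1.74857e-02,8.60733e-03,1.64762e-01,3.27045e-02
60,1.65366e-02,8.32705e-03,1.64300e-01,3.19189e-02
61,1.56530e-02,8.06026e-03,1.63842e-01,3.11967e-02
62,1.48295e-02,7.80609e-03,1.63388e-01,3.05324e-02
63,1.40611e-02,7.56375e-03,1.62937e-01,2.99212e-02
64,1.33433e-02,7.33248e-03,1.62489e-01,2.93586e-02
65,1.26722e-02,7.11161e-03,1.62045e-01,2.88406e-02
66,1.20440e-02,6.90050e-03,1.61605e-01,2.83635e-02
67,1.14555e-02,6.69856e-03,1.61167e-01,2.79242e-02
68,1.09036e-02,6.50524e-03,1.60733e-01,2.75196e-02
69,1.03855e-02,6.32004e-03,1.60302e-01,2.71469e-02
70,9.89882e-03,6.14248e-03,1.59875e-01,2.68037e-02
71,9.44114e-03,5.97212e-03,1.59450e-01,2.64878e-02
72,9.01042e-03,5.80855e-03,1.59029e-01,2.61970e-02
73,8.60472e-03,5.65140e-03,1.58611e-01,2.59294e-02
74,8.22230e-03,5.50029e-03,1.58196e-01,2.56834e-02
75,7.86152e-03,5.35490e-03,1.57784e-01,2.54574e-02
76,7.52091e-03,5.21492e-03,1.57375e-01,2.52498e-02
77,7.19910e-03,5.08005e-03,1.56969e-01,2.50593e-02
78,6.89484e-03,4.95003e-03,1.56566e-01,2.48848e-02
79,6.60696e-03,4.82460e-03,1.56165e-01,2.47250e-02
80,6.33440e-03,4.70352e-03,1.55768e-01,2.45790e-02
81,6.07617e-03,4.58657e-03,1.55374e-01,2.44457e-02
82,5.83136e-03,4.47355e-03,1.54982e-01,2.43243e-02
83,5.59912e-03,4.36425e-03,1.54593e-01,2.42140e-02
84,5.37867e-03,4.25849e-03,1.54207e-01,2.41140e-02
85,5.16929e-03,4.15611e-03,1.53823e-01,2.40236e-02
86,4.97029e-03,4.05694e-03,1.53443e-01,2.39421e-02
87,4.78106e-03,3.96083e-03,1.53065e-01,2.38690e-02
88,4.60102e-03,3.86764e-03,1.52689e-01,2.38036e-02
89,4.42962e-03,3.77723e-03,1.52316e-01,2.37455e-02
90,4.26636e-03,3.68948e-03,1.51946e-01,2.36942e-02
91,4.11078e-03,3.60428e-03,1.51578e-01,2.36492e-02
92,3.96243e-03,3.52151e-03,1.51213e-01,2.36102e-02
93,3.82091e-03,3.44107e-03,1.50850e-01,2.35766e-02
94,3.68583e-03,3.36286e-03,1.50490e-01,2.35483e-02
95,3.55684e-03,3.28679e-03,1.50132e-01,2.35247e-02
96,3.43361e-03,3.21277e-03,1.49777e-01,2.35057e-02
97,3.31583e-03,3.14072e-03,1.49424e-01,2.34909e-02
98,3.20320e-03,3.07057e-03,1.49074e-01,2.34800e-02
99,3.09545e-03,3.00224e-03,1.48725e-01,2.34728e-02
100,2.99232e-03,2.93566e-03,1.48379e-01,2.34691e-02
101,2.89358e-03,2.87077e-03,1.48036e-01,2.34685e-02
102,2.79899e-03,2.80750e-03,1.47694e-01,2.34710e-02
103,2.70835e-03,2.74581e-03,1.47355e-01,2.34764e-02
104,2.62145e-03,2.68563e-03,1.47018e-01,2.34843e-02
105,2.53811e-03,2.62691e-03,1.46683e-01,2.34947e-02
106,2.45815e-03,2.56960e-03,1.46351e-01,2.35074e-02
107,2.38140e-03,2.51366e-03,1.46021e-01,2.35223e-02
108,2.30771e-03,2.45905e-03,1.45692e-01,2.35392e-02
109,2.23693e-03,2.40571e-03,1.45366e-01,2.35579e-02
110,2.16892e-03,2.35362e-03,1.45042e-01,2.35784e-02
111,2.10355e-03,2.30272e-03,1.44720e-01,2.36006e-02
112,2.04069e-03,2.25300e-03,1.44400e-01,2.36242e-02
113,1.98023e-03,2.20441e-03,1.44082e-01,2.36493e-02
114,1.92205e-03,2.15691e-03,1.43766e-01,2.36757e-02
115,1.86606e-03,2.11049e-03,1.43453e-01,2.37033e-02
116,1.81214e-03,2.06510e-03,1.43141e-01,2.37321e-02
117,1.76022e-03,2.02073e-03,1.42831e-01,2.37619e-02
118,1.71019e-03,1.97734e-03,1.42523e-01,2.37928e-02
119,1.66198e-03,1.93490e-03,1.42216e-01,2.38245e-02
120,1.61550e-03,1.89340e-03,1.41912e-01,2.38571e-02
121,1.57068e-03,1.85280e-03,1.41610e-01,2.38904e-02
122,1.52745e-03,1.81309e-03,1.41309e-01,2.39245e-02
123,1.48573e-03,1.77424e-03,1.41011e-01,2.39593e-02
124,1.44547e-03,1.73623e-03,1.40714e-01,2.39946e-02
125,1.40661e-03,1.69904e-03,1.40419e-01,2.40306e-02
126,1.36907e-03,1.66266e-03,1.40125e-01,2.40670e-02
127,1.33282e-03,1.62705e-03,1.39834e-01,2.41039e-02
128,1.29779e-03,1.59221e-03,1.39544e-01,2.41412e-02
129,1.26393e-03,1.55811e-03,1.39256e-01,2.41790e-02
130,1.23120e-03,1.52474e-03,1.38970e-01,2.42170e-02
131,1.19956e-03,1.49209e-03,1.38685e-01,2.42554e-02
132,1.16895e-03,1.46012e-03,1.38402e-01,2.42941e-02
133,1.13934e-03,1.42884e-03,1.38121e-01,2.43330e-02
134,1.11068e-03,1.39823e-03,1.37841e-01,2.43721e-02
135,1.08295e-03,1.36826e-03,1.37564e-01,2.44115e-02
136,1.05610e-03,1.33893e-03,1.37287e-01,2.44509e-02
137,1.03010e-03,1.31022e-03,1.37013e-01,2.44906e-02
138,1.00491e-03,1.28213e-03,1.36739e-01,2.45303e-02
139,9.80514e-04,1.25462e-03,1.36468e-01,2.45702e-02
140,9.56872e-04,1.22770e-03,1.36198e-01,2.46101e-02
141,9.33958e-04,1.20135e-03,1.35929e-01,2.46501e-02
142,9.11744e-04,1.17556e-03,1.35663e-01,2.46901e-02
143,8.90204e-04,1.15032e-03,1.35397e-01,2.47301e-02
144,8.69314e-04,1.12561e-03,1.35133e-01,2.47701e-02
145,8.49050e-04,1.10142e-03,1.34871e-01,2.48101e-02
146,8.29389e-04,1.07775e-03,1.34610e-01,2.48501e-02
147,8.10308e-04,1.05458e-03,1.34351e-01,2.48900e-02
148,7.91788e-04,1.03190e-03,1.34093e-01,2.49299e-02
149,7.73809e-04,1.00970e-03,1.33836e-01,2.49697e-02
150,7.56350e-04,9.87976e-04,1.33581e-01,2.50094e-02
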