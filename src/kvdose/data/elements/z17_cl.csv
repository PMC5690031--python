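# element Cl Z=17 A=35.45
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,4.76080e+02,1.75972e+00,1.88451e-01,4.55230e+02
6,2.80875e+02,1.45153e+00,1.87739e-01,2.70626e+02
7,1.79325e+02,1.20127e+00,1.87035e-01,1.73718e+02
8,1.21342e+02,1.00224e+00,1.86337e-01,1.18023e+02
9,8.58521e+01,8.44791e-01,1.85646e-01,8.37663e+01
10,6.29265e+01,7.19779e-01,1.84962e-01,6.15519e+01
11,4.74651e+01,6.19652e-01,1.84285e-01,4.65240e+01
12,3.66639e+01,5.38574e-01,1.83614e-01,3.59989e+01
13,2.88932e+01,4.72160e-01,1.82949e-01,2.84109e+01
14,2.31620e+01,4.17145e-01,1.82291e-01,2.28044e+01
15,1.88440e+01,3.71090e-01,1.81639e-01,1.85739e+01
16,1.55300e+01,3.32165e-01,1.80993e-01,1.53227e+01
17,1.29449e+01,2.98977e-01,1.80353e-01,1.27837e+01
18,1.08994e+01,2.70457e-01,1.79719e-01,1.07727e+01
19,9.26013e+00,2.45773e-01,1.79091e-01,9.15956e+00
20,7.93136e+00,2.24270e-01,1.78469e-01,7.85095e+00
21,6.84315e+00,2.05427e-01,1.77853e-01,6.77849e+00
22,5.94362e+00,1.88827e-01,1.77242e-01,5.89143e+00
23,5.19374e+00,1.74130e-01,1.76637e-01,5.15153e+00
24,4.56377e+00,1.61058e-01,1.76037e-01,4.52962e+00
25,4.03075e+00,1.49382e-01,1.75443e-01,4.00320e+00
26,3.57682e+00,1.38913e-01,1.74854e-01,3.55470e+00
27,3.18790e+00,1.29491e-01,1.74271e-01,3.17030e+00
28,2.85281e+00,1.20982e-01,1.73692e-01,2.83899e+00
29,2.56259e+00,1.13273e-01,1.73119e-01,2.55198e+00
30,2.31001e+00,1.06269e-01,1.72551e-01,2.30213e+00
31,2.08921e+00,9.98861e-02,1.71988e-01,2.08366e+00
32,1.89535e+00,9.40543e-02,1.71430e-01,1.89183e+00
33,1.72448e+00,8.87125e-02,1.70876e-01,1.72271e+00
34,1.57330e+00,8.38079e-02,1.70328e-01,1.57307e+00
35,1.43908e+00,7.92943e-02,1.69784e-01,1.44020e+00
36,1.31952e+00,7.51318e-02,1.69245e-01,1.32183e+00
37,1.21267e+00,7.12852e-02,1.68710e-01,1.21605e+00
38,1.11691e+00,6.77235e-02,1.68181e-01,1.12124e+00
39,1.03085e+00,6.44196e-02,1.67655e-01,1.03603e+00
40,9.53285e-01,6.13494e-02,1.67134e-01,9.59245e-01
41,8.83210e-01,5.84916e-02,1.66618e-01,8.89874e-01
42,8.19744e-01,5.58271e-02,1.66106e-01,8.27052e-01
43,7.62134e-01,5.33391e-02,1.65598e-01,7.70031e-01
44,7.09722e-01,5.10124e-02,1.65094e-01,7.18164e-01
45,6.61941e-01,4.88335e-02,1.64595e-01,6.70886e-01
46,6.18293e-01,4.67903e-02,1.64099e-01,6.27705e-01
47,5.78344e-01,4.48717e-02,1.63608e-01,5.88192e-01
48,5.41714e-01,4.30679e-02,1.63121e-01,5.51969e-01
49,5.08067e-01,4.13701e-02,1.62637e-01,5.18705e-01
50,4.77109e-01,3.97701e-02,1.62158e-01,4.88106e-01
51,4.48577e-01,3.82606e-02,1.61683e-01,4.59915e-01
52,4.22241e-01,3.68350e-02,1.61211e-01,4.33902e-01
53,3.97895e-01,3.54872e-02,1.60743e-01,4.09862e-01
54,3.75356e-01,3.42117e-02,1.60279e-01,3.87615e-01
55,3.54462e-01,3.30035e-02,1.59819e-01,3.66998e-01
56,3.35065e-01,3.18580e-02,1.59362e-01,3.47868e-01
57,3.17035e-01,3.07708e-02,1.58909e-01,3.30093e-01
58,3.00255e-01,2.97383e-02,1.58459e-01,3.13559e-01
59,2.84619e-01,2.87567e-02,1.58013e-01,2.98159e-01
60,2.70033e-01,2.78229e-02,1.57570e-01,2.83801e-01
61,2.56410e-01,2.69338e-02,1.57131e-01,2.70397e-01
62,2.43673e-01,2.60866e-02,1.56695e-01,2.57873e-01
63,2.31751e-01,2.52788e-02,1.56263e-01,2.46157e-01
64,2.20582e-01,2.45079e-02,1.55833e-01,2.35187e-01
65,2.10107e-01,2.37718e-02,1.55407e-01,2.24906e-01
66,2.00273e-01,2.30684e-02,1.54985e-01,2.15260e-01
67,1.91033e-01,2.23958e-02,1.54565e-01,2.06203e-01
68,1.82342e-01,2.17523e-02,1.54149e-01,1.97691e-01
69,1.74162e-01,2.11362e-02,1.53736e-01,1.89685e-01
70,1.66455e-01,2.05460e-02,1.53326e-01,1.82147e-01
71,1.59188e-01,1.99802e-02,1.52919e-01,1.75046e-01
72,1.52331e-01,1.94376e-02,1.52515e-01,1.68351e-01
73,1.45855e-01,1.89168e-02,1.52114e-01,1.62033e-01
74,1.39734e-01,1.84167e-02,1.51716e-01,1.56066e-01
75,1.33944e-01,1.79363e-02,1.51321e-01,1.50429e-01
76,1.28465e-01,1.74745e-02,1.50928e-01,1.45097e-01
77,1.23274e-01,1.70303e-02,1.50539e-01,1.40052e-01
78,1.18354e-01,1.66029e-02,1.50152e-01,1.35275e-01
79,1.13688e-01,1.61913e-02,1.49768e-01,1.30749e-01
80,1.09259e-01,1.57949e-02,1.49387e-01,1.26458e-01
81,1.05053e-01,1.54128e-02,1.49009e-01,1.22387e-01
82,1.01057e-01,1.50444e-02,1.48633e-01,1.18522e-01
83,9.72560e-02,1.46890e-02,1.48260e-01,1.14852e-01
84,9.36401e-02,1.43460e-02,1.47890e-01,1.11364e-01
85,9.01977e-02,1.40147e-02,1.47522e-01,1.08048e-01
86,8.69188e-02,1.36946e-02,1.47157e-01,1.04892e-01
87,8.37938e-02,1.33853e-02,1.46795e-01,1.01889e-01
88,8.08140e-02,1.30862e-02,1.46435e-01,9.90291e-02
89,7.79710e-02,1.27968e-02,1.46077e-01,9.63040e-02
90,7.52572e-02,1.25167e-02,1.45722e-01,9.37063e-02
91,7.26654e-02,1.22455e-02,1.45369e-01,9.12288e-02
92,7.01890e-02,1.19827e-02,1.45019e-01,8.88650e-02
93,6.78215e-02,1.17281e-02,1.44671e-01,8.66084e-02
94,6.55572e-02,1.14812e-02,1.44326e-01,8.44534e-02
95,6.33906e-02,1.12417e-02,1.43983e-01,8.23945e-02
96,6.13165e-02,1.10093e-02,1.43642e-01,8.04266e-02
97,5.93301e-02,1.07837e-02,1.43303e-01,7.85448e-02
98,5.74268e-02,1.05646e-02,1.42967e-01,7.67448e-02
99,5.56024e-02,1.03517e-02,1.42633e-01,7.50221e-02
100,5.38529e-02,1.01448e-02,1.42301e-01,7.33730e-02
101,5.21745e-02,9.94365e-03,1.41972e-01,7.17936e-02
102,5.05637e-02,9.74797e-03,1.41644e-01,7.02805e-02
103,4.90172e-02,9.55756e-03,1.41319e-01,6.88304e-02
104,4.75318e-02,9.37222e-03,1.40996e-01,6.74401e-02
105,4.61046e-02,9.19173e-03,1.40675e-01,6.61067e-02
106,4.47327e-02,9.01592e-03,1.40356e-01,6.48275e-02
107,4.34136e-02,8.84460e-03,1.40039e-01,6.35998e-02
108,4.21448e-02,8.67760e-03,1.39724e-01,6.24212e-02
109,4.09239e-02,8.51475e-03,1.39412e-01,6.12894e-02
110,3.97487e-02,8.35591e-03,1.39101e-01,6.02022e-02
111,3.86171e-02,8.20092e-03,1.38792e-01,5.91575e-02
112,3.75272e-02,8.04964e-03,1.38485e-01,5.81533e-02
113,3.64770e-02,7.90194e-03,1.38180e-01,5.71878e-02
114,3.54648e-02,7.75769e-03,1.37877e-01,5.62593e-02
115,3.44889e-02,7.61677e-03,1.37576e-01,5.53660e-02
116,3.35477e-02,7.47907e-03,1.37277e-01,5.45065e-02
117,3.26397e-02,7.34447e-03,1.36980e-01,5.36791e-02
118,3.17635e-02,7.21287e-03,1.36684e-01,5.28826e-02
119,3.09176e-02,7.08416e-03,1.36391e-01,5.21155e-02
120,3.01009e-02,6.95826e-03,1.36099e-01,5.13765e-02
121,2.93121e-02,6.83507e-03,1.35809e-01,5.06646e-02
122,2.85500e-02,6.71451e-03,1.35521e-01,4.99784e-02
123,2.78135e-02,6.59649e-03,1.35234e-01,4.93170e-02
124,2.71015e-02,6.48093e-03,1.34950e-01,4.86792e-02
125,2.64131e-02,6.36775e-03,1.34667e-01,4.80641e-02
126,2.57473e-02,6.25689e-03,1.34386e-01,4.74708e-02
127,2.51033e-02,6.14828e-03,1.34106e-01,4.68983e-02
128,2.44800e-02,6.04184e-03,1.33828e-01,4.63459e-02
129,2.38767e-02,5.93752e-03,1.33552e-01,4.58126e-02
130,2.32927e-02,5.83525e-03,1.33277e-01,4.52977e-02
131,2.27271e-02,5.73499e-03,1.33004e-01,4.48006e-02
132,2.21793e-02,5.63666e-03,1.32733e-01,4.43204e-02
133,2.16485e-02,5.54022e-03,1.32463e-01,4.38565e-02
134,2.11342e-02,5.44562e-03,1.32195e-01,4.34082e-02
135,2.06356e-02,5.35281e-03,1.31929e-01,4.29751e-02
136,2.01523e-02,5.26174e-03,1.31664e-01,4.25564e-02
137,1.96835e-02,5.17236e-03,1.31400e-01,4.21516e-02
138,1.92289e-02,5.08465e-03,1.31138e-01,4.17602e-02
139,1.87879e-02,4.99854e-03,1.30878e-01,4.13817e-02
140,1.83599e-02,4.91401e-03,1.30619e-01,4.10155e-02
141,1.79445e-02,4.83101e-03,1.30361e-01,4.06613e-02
142,1.75413e-02,4.74951e-03,1.30105e-01,4.03186e-02
143,1.71498e-02,4.66948e-03,1.29851e-01,3.99869e-02
144,1.67696e-02,4.59087e-03,1.29598e-01,3.96658e-02
145,1.64003e-02,4.51366e-03,1.29346e-01,3.93551e-02
146,1.60415e-02,4.43781e-03,1.29096e-01,3.90542e-02
147,1.56928e-02,4.36330e-03,1.28847e-01,3.87628e-02
148,1.53539e-02,4.29009e-03,1.28600e-01,3.84806e-02
149,1.50245e-02,4.21816e-03,1.28354e-01,3.82072e-02
150,1.47042e-02,4.14747e-03,1.28109e-01,3.79424e-02
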