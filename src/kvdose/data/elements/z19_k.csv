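# element K Z=19 A=39.098
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,6.83594e+02,2.06362e+00,1.90970e-01,6.28349e+02
6,4.05374e+02,1.71449e+00,1.90248e-01,3.78075e+02
7,2.59935e+02,1.42685e+00,1.89535e-01,2.44932e+02
8,1.76548e+02,1.19540e+00,1.88828e-01,1.67633e+02
9,1.25326e+02,1.01069e+00,1.88128e-01,1.19702e+02
10,9.21314e+01,8.63076e-01,1.87434e-01,8.84119e+01
11,6.96805e+01,7.44292e-01,1.86748e-01,6.71246e+01
12,5.39556e+01,6.47785e-01,1.86068e-01,5.21428e+01
13,4.26157e+01,5.68542e-01,1.85394e-01,4.12955e+01
14,3.42338e+01,5.02779e-01,1.84727e-01,3.32505e+01
15,2.79057e+01,4.47649e-01,1.84066e-01,2.71590e+01
16,2.30397e+01,4.00997e-01,1.83412e-01,2.24632e+01
17,1.92373e+01,3.61181e-01,1.82764e-01,1.87857e+01
18,1.62236e+01,3.26933e-01,1.82121e-01,1.58653e+01
19,1.38045e+01,2.97267e-01,1.81485e-01,1.35172e+01
20,1.18407e+01,2.71403e-01,1.80855e-01,1.16080e+01
21,1.02301e+01,2.48723e-01,1.80230e-01,1.00401e+01
22,8.89700e+00,2.28728e-01,1.79611e-01,8.74064e+00
23,7.78422e+00,2.11014e-01,1.78998e-01,7.65479e+00
24,6.84821e+00,1.95249e-01,1.78390e-01,6.74051e+00
25,6.05533e+00,1.81159e-01,1.77788e-01,5.96531e+00
26,5.37932e+00,1.68518e-01,1.77191e-01,5.30383e+00
27,4.79949e+00,1.57136e-01,1.76600e-01,4.73602e+00
28,4.29938e+00,1.46853e-01,1.76014e-01,4.24595e+00
29,3.86581e+00,1.37532e-01,1.75433e-01,3.82080e+00
30,3.48811e+00,1.29059e-01,1.74857e-01,3.45023e+00
31,3.15760e+00,1.21335e-01,1.74287e-01,3.12578e+00
32,2.86716e+00,1.14275e-01,1.73721e-01,2.84053e+00
33,2.61094e+00,1.07806e-01,1.73160e-01,2.58877e+00
34,2.38405e+00,1.01864e-01,1.72604e-01,2.36574e+00
35,2.18244e+00,9.63948e-02,1.72053e-01,2.16749e+00
36,2.00269e+00,9.13491e-02,1.71507e-01,1.99069e+00
37,1.84195e+00,8.66851e-02,1.70965e-01,1.83253e+00
38,1.69777e+00,8.23655e-02,1.70429e-01,1.69062e+00
39,1.56809e+00,7.83575e-02,1.69896e-01,1.56296e+00
40,1.45114e+00,7.46321e-02,1.69368e-01,1.44780e+00
41,1.34540e+00,7.11637e-02,1.68845e-01,1.34367e+00
42,1.24956e+00,6.79293e-02,1.68326e-01,1.24928e+00
43,1.16251e+00,6.49084e-02,1.67811e-01,1.16353e+00
44,1.08327e+00,6.20830e-02,1.67301e-01,1.08545e+00
45,1.01098e+00,5.94365e-02,1.66795e-01,1.01423e+00
46,9.44896e-01,5.69543e-02,1.66293e-01,9.49116e-01
47,8.84380e-01,5.46233e-02,1.65795e-01,8.89486e-01
48,8.28856e-01,5.24314e-02,1.65301e-01,8.34775e-01
49,7.77825e-01,5.03679e-02,1.64811e-01,7.84491e-01
50,7.30843e-01,4.84230e-02,1.64326e-01,7.38199e-01
51,6.87520e-01,4.65880e-02,1.63844e-01,6.95515e-01
52,6.47509e-01,4.48546e-02,1.63366e-01,6.56096e-01
53,6.10501e-01,4.32157e-02,1.62892e-01,6.19639e-01
54,5.76222e-01,4.16645e-02,1.62421e-01,5.85875e-01
55,5.44426e-01,4.01950e-02,1.61955e-01,5.54561e-01
56,5.14894e-01,3.88014e-02,1.61492e-01,5.25481e-01
57,4.87430e-01,3.74789e-02,1.61032e-01,4.98442e-01
58,4.61857e-01,3.62225e-02,1.60577e-01,4.73270e-01
59,4.38017e-01,3.50281e-02,1.60125e-01,4.49808e-01
60,4.15765e-01,3.38916e-02,1.59676e-01,4.27915e-01
61,3.94973e-01,3.28095e-02,1.59231e-01,4.07464e-01
62,3.75524e-01,3.17782e-02,1.58789e-01,3.88339e-01
63,3.57313e-01,3.07948e-02,1.58351e-01,3.70436e-01
64,3.40242e-01,2.98563e-02,1.57916e-01,3.53659e-01
65,3.24226e-01,2.89600e-02,1.57485e-01,3.37924e-01
66,3.09183e-01,2.81035e-02,1.57056e-01,3.23151e-01
67,2.95043e-01,2.72845e-02,1.56631e-01,3.09269e-01
68,2.81738e-01,2.65008e-02,1.56209e-01,2.96213e-01
69,2.69209e-01,2.57505e-02,1.55791e-01,2.83923e-01
70,2.57400e-01,2.50316e-02,1.55375e-01,2.72344e-01
71,2.46261e-01,2.43425e-02,1.54963e-01,2.61427e-01
72,2.35745e-01,2.36815e-02,1.54553e-01,2.51126e-01
73,2.25810e-01,2.30472e-02,1.54147e-01,2.41398e-01
74,2.16417e-01,2.24381e-02,1.53744e-01,2.32205e-01
75,2.07528e-01,2.18529e-02,1.53343e-01,2.23511e-01
76,1.99112e-01,2.12904e-02,1.52946e-01,2.15284e-01
77,1.91138e-01,2.07494e-02,1.52551e-01,2.07492e-01
78,1.83576e-01,2.02288e-02,1.52159e-01,2.00109e-01
79,1.76401e-01,1.97276e-02,1.51770e-01,1.93108e-01
80,1.69590e-01,1.92448e-02,1.51384e-01,1.86464e-01
81,1.63118e-01,1.87796e-02,1.51001e-01,1.80157e-01
82,1.56966e-01,1.83310e-02,1.50620e-01,1.74165e-01
83,1.51114e-01,1.78983e-02,1.50242e-01,1.68470e-01
84,1.45545e-01,1.74807e-02,1.49867e-01,1.63053e-01
85,1.40241e-01,1.70776e-02,1.49494e-01,1.57898e-01
86,1.35187e-01,1.66881e-02,1.49124e-01,1.52990e-01
87,1.30369e-01,1.63118e-02,1.48757e-01,1.48315e-01
88,1.25774e-01,1.59479e-02,1.48392e-01,1.43858e-01
89,1.21388e-01,1.55960e-02,1.48030e-01,1.39609e-01
90,1.17199e-01,1.52554e-02,1.47670e-01,1.35554e-01
91,1.13198e-01,1.49257e-02,1.47312e-01,1.31684e-01
92,1.09374e-01,1.46064e-02,1.46957e-01,1.27989e-01
93,1.05717e-01,1.42971e-02,1.46605e-01,1.24457e-01
94,1.02218e-01,1.39972e-02,1.46255e-01,1.21082e-01
95,9.88693e-02,1.37065e-02,1.45907e-01,1.17855e-01
96,9.56625e-02,1.34244e-02,1.45562e-01,1.14767e-01
97,9.25904e-02,1.31507e-02,1.45219e-01,1.11812e-01
98,8.96459e-02,1.28849e-02,1.44878e-01,1.08982e-01
99,8.68227e-02,1.26268e-02,1.44540e-01,1.06272e-01
100,8.41146e-02,1.23760e-02,1.44203e-01,1.03675e-01
101,8.15159e-02,1.21323e-02,1.43869e-01,1.01186e-01
102,7.90211e-02,1.18953e-02,1.43538e-01,9.87984e-02
103,7.66252e-02,1.16647e-02,1.43208e-01,9.65082e-02
104,7.43233e-02,1.14404e-02,1.42881e-01,9.43103e-02
105,7.21110e-02,1.12221e-02,1.42555e-01,9.22004e-02
106,6.99840e-02,1.10094e-02,1.42232e-01,9.01742e-02
107,6.79382e-02,1.08023e-02,1.41911e-01,8.82276e-02
108,6.59698e-02,1.06005e-02,1.41592e-01,8.63570e-02
109,6.40753e-02,1.04038e-02,1.41275e-01,8.45588e-02
110,6.22512e-02,1.02120e-02,1.40960e-01,8.28296e-02
111,6.04944e-02,1.00249e-02,1.40647e-01,8.11663e-02
112,5.88018e-02,9.84240e-03,1.40336e-01,7.95658e-02
113,5.71705e-02,9.66426e-03,1.40027e-01,7.80254e-02
114,5.55979e-02,9.49034e-03,1.39720e-01,7.65423e-02
115,5.40812e-02,9.32050e-03,1.39415e-01,7.51139e-02
116,5.26181e-02,9.15458e-03,1.39112e-01,7.37380e-02
117,5.12063e-02,8.99246e-03,1.38811e-01,7.24120e-02
118,4.98436e-02,8.83401e-03,1.38511e-01,7.11340e-02
119,4.85278e-02,8.67909e-03,1.38214e-01,6.99018e-02
120,4.72570e-02,8.52760e-03,1.37918e-01,6.87135e-02
121,4.60293e-02,8.37941e-03,1.37624e-01,6.75672e-02
122,4.48429e-02,8.23441e-03,1.37332e-01,6.64612e-02
123,4.36961e-02,8.09252e-03,1.37042e-01,6.53937e-02
124,4.25873e-02,7.95361e-03,1.36753e-01,6.43631e-02
125,4.15149e-02,7.81761e-03,1.36467e-01,6.33680e-02
126,4.04776e-02,7.68441e-03,1.36182e-01,6.24069e-02
127,3.94737e-02,7.55394e-03,1.35898e-01,6.14784e-02
128,3.85022e-02,7.42611e-03,1.35617e-01,6.05812e-02
129,3.75615e-02,7.30084e-03,1.35337e-01,5.97140e-02
130,3.66507e-02,7.17806e-03,1.35059e-01,5.88757e-02
131,3.57685e-02,7.05769e-03,1.34782e-01,5.80651e-02
132,3.49137e-02,6.93967e-03,1.34507e-01,5.72812e-02
133,3.40855e-02,6.82392e-03,1.34234e-01,5.65228e-02
134,3.32826e-02,6.71039e-03,1.33962e-01,5.57891e-02
135,3.25043e-02,6.59901e-03,1.33692e-01,5.50790e-02
136,3.17495e-02,6.48973e-03,1.33423e-01,5.43916e-02
137,3.10175e-02,6.38249e-03,1.33156e-01,5.37262e-02
138,3.03072e-02,6.27723e-03,1.32891e-01,5.30818e-02
139,2.96181e-02,6.17390e-03,1.32627e-01,5.24578e-02
140,2.89493e-02,6.07246e-03,1.32365e-01,5.18532e-02
141,2.83000e-02,5.97286e-03,1.32104e-01,5.12675e-02
142,2.76695e-02,5.87505e-03,1.31844e-01,5.06999e-02
143,2.70573e-02,5.77898e-03,1.31587e-01,5.01498e-02
144,2.64626e-02,5.68462e-03,1.31330e-01,4.96165e-02
145,2.58849e-02,5.59192e-03,1.31075e-01,4.90994e-02
146,2.53234e-02,5.50085e-03,1.30822e-01,4.85980e-02
147,2.47778e-02,5.41137e-03,1.30569e-01,4.81117e-02
148,2.42474e-02,5.32344e-03,1.30319e-01,4.76399e-02
149,2.37316e-02,5.23702e-03,1.30069e-01,4.71822e-02
150,2.32301e-02,5.15209e-03,1.29822e-01,4.67380e-02
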