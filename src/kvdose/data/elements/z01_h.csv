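# element H Z=1 A=1.008
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,1.37417e-01,5.85247e-02,3.89856e-01,1.41151e-01
6,7.11574e-02,4.30371e-02,3.88384e-01,7.56030e-02
7,4.06864e-02,3.29155e-02,3.86927e-01,4.58319e-02
8,2.50222e-02,2.59479e-02,3.85484e-01,3.08566e-02
9,1.62730e-02,2.09536e-02,3.84054e-01,2.27854e-02
10,1.10614e-02,1.72565e-02,3.82639e-01,1.82411e-02
11,7.79356e-03,1.44465e-02,3.81238e-01,1.56301e-02
12,5.65668e-03,1.22632e-02,3.79849e-01,1.41398e-02
13,4.20966e-03,1.05347e-02,3.78475e-01,1.33294e-02
14,3.20038e-03,9.14385e-03,3.77113e-01,1.29468e-02
15,2.47833e-03,8.00882e-03,3.75764e-01,1.28418e-02
16,1.95030e-03,7.07096e-03,3.74428e-01,1.29213e-02
17,1.55665e-03,6.28744e-03,3.73104e-01,1.31259e-02
18,1.25816e-03,5.62637e-03,3.71793e-01,1.34166e-02
19,1.02837e-03,5.06369e-03,3.70494e-01,1.37670e-02
20,8.49067e-04,4.58092e-03,3.69207e-01,1.41591e-02
21,7.07440e-04,4.16372e-03,3.67932e-01,1.45803e-02
22,5.94333e-04,3.80081e-03,3.66668e-01,1.50215e-02
23,5.03091e-04,3.48324e-03,3.65416e-01,1.54763e-02
24,4.28810e-04,3.20382e-03,3.64176e-01,1.59400e-02
25,3.67826e-04,2.95671e-03,3.62947e-01,1.64089e-02
26,3.17371e-04,2.73715e-03,3.61728e-01,1.68806e-02
27,2.75326e-04,2.54121e-03,3.60521e-01,1.73529e-02
28,2.40057e-04,2.36564e-03,3.59325e-01,1.78245e-02
29,2.10289e-04,2.20771e-03,3.58139e-01,1.82941e-02
30,1.85020e-04,2.06511e-03,3.56964e-01,1.87610e-02
31,1.63454e-04,1.93591e-03,3.55799e-01,1.92245e-02
32,1.44957e-04,1.81846e-03,3.54644e-01,1.96840e-02
33,1.29017e-04,1.71133e-03,3.53499e-01,2.01391e-02
34,1.15219e-04,1.61330e-03,3.52364e-01,2.05896e-02
35,1.03226e-04,1.52334e-03,3.51240e-01,2.10353e-02
36,9.27610e-05,1.44052e-03,3.50124e-01,2.14760e-02
37,8.35950e-05,1.36407e-03,3.49019e-01,2.19116e-02
38,7.55388e-05,1.29330e-03,3.47923e-01,2.23419e-02
39,6.84342e-05,1.22761e-03,3.46836e-01,2.27671e-02
40,6.21490e-05,1.16647e-03,3.45758e-01,2.31870e-02
41,5.65721e-05,1.10944e-03,3.44690e-01,2.36016e-02
42,5.16095e-05,1.05611e-03,3.43630e-01,2.40110e-02
43,4.71813e-05,1.00612e-03,3.42579e-01,2.44151e-02
44,4.32199e-05,9.59175e-04,3.41538e-01,2.48140e-02
45,3.96672e-05,9.14993e-04,3.40504e-01,2.52078e-02
46,3.64735e-05,8.73336e-04,3.39479e-01,2.55965e-02
47,3.35959e-05,8.33990e-04,3.38463e-01,2.59801e-02
48,3.09976e-05,7.96768e-04,3.37455e-01,2.63587e-02
49,2.86466e-05,7.61503e-04,3.36455e-01,2.67323e-02
50,2.65150e-05,7.28045e-04,3.35464e-01,2.71011e-02
51,2.45786e-05,6.96262e-04,3.34480e-01,2.74650e-02
52,2.28164e-05,6.66036e-04,3.33504e-01,2.78241e-02
53,2.12098e-05,6.37262e-04,3.32536e-01,2.81786e-02
54,1.97426e-05,6.09844e-04,3.31576e-01,2.85284e-02
55,1.84004e-05,5.83698e-04,3.30624e-01,2.88737e-02
56,1.71707e-05,5.58745e-04,3.29679e-01,2.92144e-02
57,1.60423e-05,5.34915e-04,3.28741e-01,2.95507e-02
58,1.50053e-05,5.12147e-04,3.27811e-01,2.98827e-02
59,1.40510e-05,4.90380e-04,3.26888e-01,3.02103e-02
60,1.31716e-05,4.69563e-04,3.25972e-01,3.05337e-02
61,1.23600e-05,4.49647e-04,3.25064e-01,3.08529e-02
62,1.16102e-05,4.30586e-04,3.24162e-01,3.11680e-02
63,1.09165e-05,4.12339e-04,3.23267e-01,3.14790e-02
64,1.02739e-05,3.94868e-04,3.22379e-01,3.17861e-02
65,9.67807e-06,3.78137e-04,3.21498e-01,3.20892e-02
66,9.12488e-06,3.62112e-04,3.20624e-01,3.23884e-02
67,8.61073e-06,3.46761e-04,3.19756e-01,3.26838e-02
68,8.13235e-06,3.32056e-04,3.18895e-01,3.29754e-02
69,7.68681e-06,3.17968e-04,3.18040e-01,3.32634e-02
70,7.27141e-06,3.04471e-04,3.17192e-01,3.35477e-02
71,6.88375e-06,2.91540e-04,3.16350e-01,3.38284e-02
72,6.52163e-06,2.79151e-04,3.15514e-01,3.41056e-02
73,6.18304e-06,2.67282e-04,3.14684e-01,3.43793e-02
74,5.86618e-06,2.55911e-04,3.13861e-01,3.46496e-02
75,5.56939e-06,2.45019e-04,3.13043e-01,3.49165e-02
76,5.29115e-06,2.34584e-04,3.12232e-01,3.51801e-02
77,5.03011e-06,2.24589e-04,3.11426e-01,3.54404e-02
78,4.78498e-06,2.15016e-04,3.10627e-01,3.56975e-02
79,4.55463e-06,2.05847e-04,3.09833e-01,3.59514e-02
80,4.33798e-06,1.97067e-04,3.09044e-01,3.62022e-02
81,4.13408e-06,1.88658e-04,3.08262e-01,3.64499e-02
82,3.94204e-06,1.80607e-04,3.07484e-01,3.66946e-02
83,3.76102e-06,1.72898e-04,3.06713e-01,3.69363e-02
84,3.59029e-06,1.65517e-04,3.05947e-01,3.71750e-02
85,3.42915e-06,1.58452e-04,3.05186e-01,3.74108e-02
86,3.27695e-06,1.51688e-04,3.04431e-01,3.76438e-02
87,3.13311e-06,1.45213e-04,3.03681e-01,3.78740e-02
88,2.99709e-06,1.39017e-04,3.02936e-01,3.81014e-02
89,2.86837e-06,1.33086e-04,3.02196e-01,3.83260e-02
90,2.74649e-06,1.27410e-04,3.01461e-01,3.85480e-02
91,2.63102e-06,1.21979e-04,3.00732e-01,3.87673e-02
92,2.52156e-06,1.16781e-04,3.00007e-01,3.89840e-02
93,2.41773e-06,1.11808e-04,2.99288e-01,3.91981e-02
94,2.31920e-06,1.07050e-04,2.98573e-01,3.94097e-02
95,2.22564e-06,1.02497e-04,2.97863e-01,3.96188e-02
96,2.13675e-06,9.81413e-05,2.97158e-01,3.98254e-02
97,2.05225e-06,9.39742e-05,2.96458e-01,4.00296e-02
98,1.97189e-06,8.99877e-05,2.95762e-01,4.02314e-02
99,1.89543e-06,8.61741e-05,2.95071e-01,4.04308e-02
100,1.82264e-06,8.25259e-05,2.94385e-01,4.06279e-02
101,1.75331e-06,7.90361e-05,2.93703e-01,4.08227e-02
102,1.68724e-06,7.56978e-05,2.93026e-01,4.10153e-02
103,1.62426e-06,7.25044e-05,2.92353e-01,4.12056e-02
104,1.56419e-06,6.94498e-05,2.91685e-01,4.13937e-02
105,1.50687e-06,6.65279e-05,2.91020e-01,4.15797e-02
106,1.45215e-06,6.37329e-05,2.90361e-01,4.17635e-02
107,1.39989e-06,6.10592e-05,2.89705e-01,4.19452e-02
108,1.34996e-06,5.85018e-05,2.89054e-01,4.21248e-02
109,1.30224e-06,5.60553e-05,2.88407e-01,4.23024e-02
110,1.25660e-06,5.37150e-05,2.87764e-01,4.24780e-02
111,1.21295e-06,5.14763e-05,2.87125e-01,4.26515e-02
112,1.17118e-06,4.93346e-05,2.86491e-01,4.28231e-02
113,1.13118e-06,4.72858e-05,2.85860e-01,4.29928e-02
114,1.09288e-06,4.53257e-05,2.85233e-01,4.31605e-02
115,1.05619e-06,4.34504e-05,2.84610e-01,4.33264e-02
116,1.02102e-06,4.16563e-05,2.83991e-01,4.34904e-02
117,9.87304e-07,3.99396e-05,2.83376e-01,4.36526e-02
118,9.54967e-07,3.82971e-05,2.82765e-01,4.38130e-02
119,9.23941e-07,3.67254e-05,2.82158e-01,4.39715e-02
120,8.94165e-07,3.52214e-05,2.81554e-01,4.41284e-02
121,8.65577e-07,3.37821e-05,2.80954e-01,4.42834e-02
122,8.38122e-07,3.24047e-05,2.80358e-01,4.44368e-02
123,8.11746e-07,3.10864e-05,2.79765e-01,4.45885e-02
124,7.86399e-07,2.98246e-05,2.79176e-01,4.47385e-02
125,7.62032e-07,2.86168e-05,2.78591e-01,4.48868e-02
126,7.38601e-07,2.74607e-05,2.78009e-01,4.50336e-02
127,7.16063e-07,2.63540e-05,2.77431e-01,4.51787e-02
128,6.94377e-07,2.52944e-05,2.76856e-01,4.53222e-02
129,6.73504e-07,2.42799e-05,2.76285e-01,4.54642e-02
130,6.53410e-07,2.33085e-05,2.75717e-01,4.56047e-02
131,6.34058e-07,2.23783e-05,2.75152e-01,4.57436e-02
132,6.15417e-07,2.14876e-05,2.74591e-01,4.58810e-02
133,5.97454e-07,2.06344e-05,2.74033e-01,4.60170e-02
134,5.80142e-07,1.98173e-05,2.73478e-01,4.61514e-02
135,5.63451e-07,1.90346e-05,2.72926e-01,4.62845e-02
136,5.47356e-07,1.82848e-05,2.72378e-01,4.64161e-02
137,5.31830e-07,1.75664e-05,2.71833e-01,4.65463e-02
138,5.16850e-07,1.68782e-05,2.71291e-01,4.66751e-02
139,5.02393e-07,1.62187e-05,2.70753e-01,4.68025e-02
140,4.88437e-07,1.55867e-05,2.70217e-01,4.69286e-02
141,4.74962e-07,1.49810e-05,2.69684e-01,4.70533e-02
142,4.61948e-07,1.44005e-05,2.69155e-01,4.71768e-02
143,4.49375e-07,1.38440e-05,2.68628e-01,4.72989e-02
144,4.37227e-07,1.33105e-05,2.68105e-01,4.74197e-02
145,4.25486e-07,1.27991e-05,2.67584e-01,4.75393e-02
146,4.14136e-07,1.23087e-05,2.67067e-01,4.76576e-02
147,4.03161e-07,1.18385e-05,2.66552e-01,4.77746e-02
148,3.92546e-07,1.13875e-05,2.66040e-01,4.78905e-02
149,3.82278e-07,1.09550e-05,2.65531e-01,4.80051e-02
150,3.72343e-07,1.05401e-05,2.65025e-01,4.81186e-02
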