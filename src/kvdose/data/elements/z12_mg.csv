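# element Mg Z=12 A=24.305
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,1.64577e+02,1.13592e+00,1.94022e-01,1.63549e+02
6,9.55513e+01,9.16699e-01,1.93289e-01,9.50555e+01
7,6.01834e+01,7.46408e-01,1.92564e-01,5.99171e+01
8,4.02481e+01,6.15491e-01,1.91846e-01,4.00937e+01
9,2.81829e+01,5.14456e-01,1.91134e-01,2.80882e+01
10,2.04665e+01,4.35616e-01,1.90430e-01,2.04060e+01
11,1.53089e+01,3.73231e-01,1.89733e-01,1.52693e+01
12,1.17350e+01,3.23145e-01,1.89042e-01,1.17086e+01
13,9.18295e+00,2.82376e-01,1.88357e-01,9.16540e+00
14,7.31363e+00,2.48766e-01,1.87680e-01,7.30214e+00
15,5.91417e+00,2.20743e-01,1.87008e-01,5.90700e+00
16,4.84647e+00,1.97138e-01,1.86343e-01,4.84246e+00
17,4.01826e+00,1.77073e-01,1.85685e-01,4.01662e+00
18,3.36634e+00,1.59878e-01,1.85032e-01,3.36655e+00
19,2.84648e+00,1.45034e-01,1.84386e-01,2.84813e+00
20,2.42705e+00,1.32135e-01,1.83745e-01,2.42988e+00
21,2.08508e+00,1.20856e-01,1.83111e-01,2.08888e+00
22,1.80361e+00,1.10941e-01,1.82482e-01,1.80822e+00
23,1.56990e+00,1.02180e-01,1.81859e-01,1.57522e+00
24,1.37433e+00,9.44027e-02,1.81241e-01,1.38026e+00
25,1.20947e+00,8.74680e-02,1.80630e-01,1.21594e+00
26,1.06956e+00,8.12598e-02,1.80023e-01,1.07652e+00
27,9.50105e-01,7.56812e-02,1.79423e-01,9.57504e-01
28,8.47520e-01,7.06506e-02,1.78827e-01,8.55325e-01
29,7.58955e-01,6.60993e-02,1.78237e-01,7.67136e-01
30,6.82114e-01,6.19689e-02,1.77652e-01,6.90648e-01
31,6.15136e-01,5.82094e-02,1.77072e-01,6.24002e-01
32,5.56502e-01,5.47782e-02,1.76498e-01,5.65682e-01
33,5.04963e-01,5.16385e-02,1.75928e-01,5.14443e-01
34,4.59487e-01,4.87584e-02,1.75363e-01,4.69254e-01
35,4.19217e-01,4.61104e-02,1.74803e-01,4.29260e-01
36,3.83436e-01,4.36704e-02,1.74248e-01,3.93744e-01
37,3.51540e-01,4.14174e-02,1.73698e-01,3.62106e-01
38,3.23022e-01,3.93328e-02,1.73153e-01,3.33838e-01
39,2.97450e-01,3.74004e-02,1.72612e-01,3.08508e-01
40,2.74458e-01,3.56059e-02,1.72075e-01,2.85752e-01
41,2.53731e-01,3.39366e-02,1.71544e-01,2.65255e-01
42,2.35000e-01,3.23811e-02,1.71016e-01,2.46749e-01
43,2.18032e-01,3.09294e-02,1.70493e-01,2.30001e-01
44,2.02628e-01,2.95727e-02,1.69975e-01,2.14812e-01
45,1.88613e-01,2.83027e-02,1.69461e-01,2.01008e-01
46,1.75836e-01,2.71124e-02,1.68951e-01,1.88437e-01
47,1.64164e-01,2.59952e-02,1.68445e-01,1.76968e-01
48,1.53482e-01,2.49454e-02,1.67943e-01,1.66485e-01
49,1.43688e-01,2.39576e-02,1.67446e-01,1.56886e-01
50,1.34693e-01,2.30272e-02,1.66952e-01,1.48083e-01
51,1.26418e-01,2.21498e-02,1.66462e-01,1.39997e-01
52,1.18793e-01,2.13214e-02,1.65977e-01,1.32558e-01
53,1.11756e-01,2.05386e-02,1.65495e-01,1.25703e-01
54,1.05252e-01,1.97980e-02,1.65017e-01,1.19380e-01
55,9.92331e-02,1.90968e-02,1.64543e-01,1.13537e-01
56,9.36543e-02,1.84322e-02,1.64073e-01,1.08133e-01
57,8.84770e-02,1.78017e-02,1.63606e-01,1.03127e-01
58,8.36660e-02,1.72030e-02,1.63143e-01,9.84853e-02
59,7.91900e-02,1.66340e-02,1.62684e-01,9.41759e-02
60,7.50206e-02,1.60929e-02,1.62228e-01,9.01708e-02
61,7.11324e-02,1.55778e-02,1.61776e-01,8.64445e-02
62,6.75023e-02,1.50872e-02,1.61327e-01,8.29740e-02
63,6.41095e-02,1.46194e-02,1.60882e-01,7.97386e-02
64,6.09352e-02,1.41731e-02,1.60440e-01,7.67195e-02
65,5.79623e-02,1.37470e-02,1.60002e-01,7.38996e-02
66,5.51753e-02,1.33399e-02,1.59567e-01,7.12635e-02
67,5.25601e-02,1.29506e-02,1.59135e-01,6.87972e-02
68,5.01037e-02,1.25782e-02,1.58706e-01,6.64877e-02
69,4.77946e-02,1.22216e-02,1.58281e-01,6.43234e-02
70,4.56218e-02,1.18801e-02,1.57859e-01,6.22937e-02
71,4.35757e-02,1.15526e-02,1.57440e-01,6.03887e-02
72,4.16473e-02,1.12385e-02,1.57024e-01,5.85995e-02
73,3.98284e-02,1.09369e-02,1.56611e-01,5.69180e-02
74,3.81113e-02,1.06473e-02,1.56201e-01,5.53365e-02
75,3.64892e-02,1.03690e-02,1.55794e-01,5.38483e-02
76,3.49556e-02,1.01014e-02,1.55390e-01,5.24469e-02
77,3.35047e-02,9.84384e-03,1.54989e-01,5.11264e-02
78,3.21311e-02,9.59590e-03,1.54591e-01,4.98816e-02
79,3.08297e-02,9.35706e-03,1.54196e-01,4.87074e-02
80,2.95960e-02,9.12685e-03,1.53804e-01,4.75992e-02
81,2.84256e-02,8.90483e-03,1.53414e-01,4.65528e-02
82,2.73146e-02,8.69059e-03,1.53027e-01,4.55643e-02
83,2.62594e-02,8.48375e-03,1.52643e-01,4.46299e-02
84,2.52564e-02,8.28395e-03,1.52262e-01,4.37463e-02
85,2.43027e-02,8.09084e-03,1.51884e-01,4.29105e-02
86,2.33951e-02,7.90410e-03,1.51508e-01,4.21194e-02
87,2.25311e-02,7.72342e-03,1.51134e-01,4.13704e-02
88,2.17080e-02,7.54853e-03,1.50764e-01,4.06609e-02
89,2.09235e-02,7.37915e-03,1.50396e-01,3.99887e-02
90,2.01754e-02,7.21504e-03,1.50030e-01,3.93515e-02
91,1.94617e-02,7.05594e-03,1.49667e-01,3.87472e-02
92,1.87804e-02,6.90163e-03,1.49306e-01,3.81741e-02
93,1.81297e-02,6.75190e-03,1.48948e-01,3.76303e-02
94,1.75079e-02,6.60655e-03,1.48592e-01,3.71142e-02
95,1.69135e-02,6.46539e-03,1.48239e-01,3.66242e-02
96,1.63451e-02,6.32823e-03,1.47888e-01,3.61588e-02
97,1.58011e-02,6.19491e-03,1.47540e-01,3.57168e-02
98,1.52805e-02,6.06527e-03,1.47194e-01,3.52968e-02
99,1.47818e-02,5.93915e-03,1.46850e-01,3.48976e-02
100,1.43040e-02,5.81641e-03,1.46508e-01,3.45182e-02
101,1.38461e-02,5.69692e-03,1.46169e-01,3.41574e-02
102,1.34070e-02,5.58054e-03,1.45832e-01,3.38144e-02
103,1.29858e-02,5.46715e-03,1.45497e-01,3.34881e-02
104,1.25816e-02,5.35664e-03,1.45164e-01,3.31777e-02
105,1.21936e-02,5.24890e-03,1.44834e-01,3.28824e-02
106,1.18209e-02,5.14382e-03,1.44505e-01,3.26013e-02
107,1.14628e-02,5.04131e-03,1.44179e-01,3.23339e-02
108,1.11187e-02,4.94127e-03,1.43855e-01,3.20793e-02
109,1.07879e-02,4.84361e-03,1.43533e-01,3.18370e-02
110,1.04696e-02,4.74825e-03,1.43213e-01,3.16063e-02
111,1.01635e-02,4.65511e-03,1.42895e-01,3.13866e-02
112,9.86885e-03,4.56411e-03,1.42579e-01,3.11775e-02
113,9.58518e-03,4.47518e-03,1.42265e-01,3.09784e-02
114,9.31198e-03,4.38826e-03,1.41953e-01,3.07888e-02
115,9.04878e-03,4.30327e-03,1.41644e-01,3.06083e-02
116,8.79514e-03,4.22016e-03,1.41336e-01,3.04364e-02
117,8.55063e-03,4.13887e-03,1.41029e-01,3.02727e-02
118,8.31486e-03,4.05933e-03,1.40725e-01,3.01168e-02
119,8.08744e-03,3.98151e-03,1.40423e-01,2.99684e-02
120,7.86801e-03,3.90533e-03,1.40123e-01,2.98271e-02
121,7.65623e-03,3.83077e-03,1.39824e-01,2.96926e-02
122,7.45177e-03,3.75776e-03,1.39527e-01,2.95645e-02
123,7.25433e-03,3.68627e-03,1.39232e-01,2.94427e-02
124,7.06360e-03,3.61626e-03,1.38939e-01,2.93267e-02
125,6.87932e-03,3.54767e-03,1.38648e-01,2.92163e-02
126,6.70122e-03,3.48048e-03,1.38358e-01,2.91113e-02
127,6.52904e-03,3.41465e-03,1.38071e-01,2.90114e-02
128,6.36255e-03,3.35014e-03,1.37784e-01,2.89164e-02
129,6.20151e-03,3.28691e-03,1.37500e-01,2.88261e-02
130,6.04570e-03,3.22494e-03,1.37217e-01,2.87402e-02
131,5.89493e-03,3.16419e-03,1.36936e-01,2.86587e-02
132,5.74899e-03,3.10464e-03,1.36657e-01,2.85812e-02
133,5.60769e-03,3.04624e-03,1.36379e-01,2.85076e-02
134,5.47085e-03,2.98899e-03,1.36103e-01,2.84377e-02
135,5.33830e-03,2.93284e-03,1.35829e-01,2.83714e-02
136,5.20988e-03,2.87778e-03,1.35556e-01,2.83085e-02
137,5.08543e-03,2.82377e-03,1.35285e-01,2.82489e-02
138,4.96479e-03,2.77080e-03,1.35015e-01,2.81924e-02
139,4.84784e-03,2.71884e-03,1.34747e-01,2.81390e-02
140,4.73442e-03,2.66787e-03,1.34480e-01,2.80883e-02
141,4.62442e-03,2.61786e-03,1.34215e-01,2.80404e-02
142,4.51769e-03,2.56881e-03,1.33952e-01,2.79952e-02
143,4.41414e-03,2.52068e-03,1.33690e-01,2.79524e-02
144,4.31363e-03,2.47345e-03,1.33429e-01,2.79121e-02
145,4.21606e-03,2.42712e-03,1.33170e-01,2.78741e-02
146,4.12133e-03,2.38165e-03,1.32913e-01,2.78382e-02
147,4.02933e-03,2.33704e-03,1.32656e-01,2.78045e-02
148,3.93997e-03,2.29326e-03,1.32402e-01,2.77729e-02
149,3.85316e-03,2.25029e-03,1.32148e-01,2.77431e-02
150,3.76881e-03,2.20813e-03,1.31897e-01,2.77153e-02
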