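# element Ca Z=20 A=40.078
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,8.24369e+02,2.26561e+00,1.96105e-01,7.37556e+02
6,4.90010e+02,1.88859e+00,1.95365e-01,4.47009e+02
7,3.14834e+02,1.57588e+00,1.94632e-01,2.91154e+02
8,2.14206e+02,1.32288e+00,1.93906e-01,2.00110e+02
9,1.52289e+02,1.12012e+00,1.93187e-01,1.43383e+02
10,1.12106e+02,9.57566e-01,1.92475e-01,1.06207e+02
11,8.48927e+01,8.26463e-01,1.91770e-01,8.08329e+01
12,6.58089e+01,7.19772e-01,1.91071e-01,6.29255e+01
13,5.20317e+01,6.32060e-01,1.90380e-01,4.99288e+01
14,4.18380e+01,5.59204e-01,1.89695e-01,4.02693e+01
15,3.41348e+01,4.98084e-01,1.89016e-01,3.29417e+01
16,2.82062e+01,4.46335e-01,1.88344e-01,2.72834e+01
17,2.35696e+01,4.02147e-01,1.87678e-01,2.28454e+01
18,1.98919e+01,3.64122e-01,1.87019e-01,1.93161e+01
19,1.69377e+01,3.31171e-01,1.86365e-01,1.64747e+01
20,1.45378e+01,3.02433e-01,1.85718e-01,1.41618e+01
21,1.25683e+01,2.77224e-01,1.85077e-01,1.22602e+01
22,1.09371e+01,2.54992e-01,1.84441e-01,1.06826e+01
23,9.57466e+00,2.35290e-01,1.83811e-01,9.36299e+00
24,8.42801e+00,2.17751e-01,1.83187e-01,8.25090e+00
25,7.45616e+00,2.02072e-01,1.82569e-01,7.30719e+00
26,6.62713e+00,1.88002e-01,1.81956e-01,6.50125e+00
27,5.91569e+00,1.75329e-01,1.81349e-01,5.80891e+00
28,5.30177e+00,1.63877e-01,1.80747e-01,5.21091e+00
29,4.76928e+00,1.53495e-01,1.80151e-01,4.69178e+00
30,4.30520e+00,1.44056e-01,1.79559e-01,4.23898e+00
31,3.89892e+00,1.35449e-01,1.78973e-01,3.84228e+00
32,3.54176e+00,1.27580e-01,1.78393e-01,3.49330e+00
33,3.22653e+00,1.20369e-01,1.77817e-01,3.18511e+00
34,2.94728e+00,1.13745e-01,1.77246e-01,2.91194e+00
35,2.69905e+00,1.07646e-01,1.76680e-01,2.66898e+00
36,2.47767e+00,1.02020e-01,1.76119e-01,2.45219e+00
37,2.27961e+00,9.68176e-02,1.75563e-01,2.25815e+00
38,2.10190e+00,9.19992e-02,1.75012e-01,2.08397e+00
39,1.94200e+00,8.75279e-02,1.74465e-01,1.92720e+00
40,1.79775e+00,8.33715e-02,1.73923e-01,1.78572e+00
41,1.66729e+00,7.95012e-02,1.73386e-01,1.65772e+00
42,1.54901e+00,7.58918e-02,1.72853e-01,1.54164e+00
43,1.44154e+00,7.25204e-02,1.72324e-01,1.43614e+00
44,1.34367e+00,6.93668e-02,1.71800e-01,1.34005e+00
45,1.25437e+00,6.64127e-02,1.71280e-01,1.25235e+00
46,1.17271e+00,6.36417e-02,1.70765e-01,1.17215e+00
47,1.09791e+00,6.10393e-02,1.70253e-01,1.09866e+00
48,1.02926e+00,5.85921e-02,1.69746e-01,1.03121e+00
49,9.66150e-01,5.62880e-02,1.69243e-01,9.69201e-01
50,9.08031e-01,5.41163e-02,1.68745e-01,9.12088e-01
51,8.54424e-01,5.20670e-02,1.68250e-01,8.59406e-01
52,8.04902e-01,5.01312e-02,1.67759e-01,8.10736e-01
53,7.59086e-01,4.83008e-02,1.67272e-01,7.65708e-01
54,7.16637e-01,4.65682e-02,1.66789e-01,7.23989e-01
55,6.77254e-01,4.49267e-02,1.66310e-01,6.85285e-01
56,6.40667e-01,4.33701e-02,1.65835e-01,6.49329e-01
57,6.06633e-01,4.18926e-02,1.65363e-01,6.15886e-01
58,5.74936e-01,4.04890e-02,1.64895e-01,5.84740e-01
59,5.45379e-01,3.91546e-02,1.64431e-01,5.55701e-01
60,5.17786e-01,3.78848e-02,1.63970e-01,5.28594e-01
61,4.91997e-01,3.66757e-02,1.63513e-01,5.03264e-01
62,4.67870e-01,3.55234e-02,1.63060e-01,4.79568e-01
63,4.45272e-01,3.44245e-02,1.62610e-01,4.57379e-01
64,4.24086e-01,3.33757e-02,1.62163e-01,4.36580e-01
65,4.04203e-01,3.23741e-02,1.61720e-01,4.17065e-01
66,3.85527e-01,3.14169e-02,1.61280e-01,3.98738e-01
67,3.67966e-01,3.05015e-02,1.60843e-01,3.81511e-01
68,3.51441e-01,2.96256e-02,1.60410e-01,3.65302e-01
69,3.35875e-01,2.87870e-02,1.59980e-01,3.50041e-01
70,3.21202e-01,2.79835e-02,1.59554e-01,3.35658e-01
71,3.07359e-01,2.72132e-02,1.59130e-01,3.22092e-01
72,2.94287e-01,2.64744e-02,1.58710e-01,3.09287e-01
73,2.81935e-01,2.57653e-02,1.58292e-01,2.97192e-01
74,2.70254e-01,2.50845e-02,1.57878e-01,2.85758e-01
75,2.59200e-01,2.44303e-02,1.57467e-01,2.74941e-01
76,2.48731e-01,2.38015e-02,1.57059e-01,2.64701e-01
77,2.38810e-01,2.31968e-02,1.56653e-01,2.55001e-01
78,2.29400e-01,2.26148e-02,1.56251e-01,2.45806e-01
79,2.20471e-01,2.20546e-02,1.55852e-01,2.37084e-01
80,2.11992e-01,2.15149e-02,1.55455e-01,2.28805e-01
81,2.03936e-01,2.09949e-02,1.55061e-01,2.20943e-01
82,1.96275e-01,2.04935e-02,1.54671e-01,2.13471e-01
83,1.88988e-01,2.00099e-02,1.54282e-01,2.06367e-01
84,1.82051e-01,1.95432e-02,1.53897e-01,1.99607e-01
85,1.75443e-01,1.90927e-02,1.53514e-01,1.93173e-01
86,1.69147e-01,1.86575e-02,1.53134e-01,1.87045e-01
87,1.63143e-01,1.82369e-02,1.52757e-01,1.81205e-01
88,1.57415e-01,1.78304e-02,1.52382e-01,1.75637e-01
89,1.51948e-01,1.74372e-02,1.52010e-01,1.70326e-01
90,1.46727e-01,1.70567e-02,1.51641e-01,1.65257e-01
91,1.41738e-01,1.66884e-02,1.51274e-01,1.60417e-01
92,1.36969e-01,1.63318e-02,1.50909e-01,1.55793e-01
93,1.32407e-01,1.59863e-02,1.50547e-01,1.51374e-01
94,1.28043e-01,1.56515e-02,1.50188e-01,1.47148e-01
95,1.23865e-01,1.53268e-02,1.49831e-01,1.43106e-01
96,1.19864e-01,1.50119e-02,1.49476e-01,1.39238e-01
97,1.16030e-01,1.47064e-02,1.49124e-01,1.35535e-01
98,1.12355e-01,1.44098e-02,1.48774e-01,1.31988e-01
99,1.08831e-01,1.41217e-02,1.48427e-01,1.28589e-01
100,1.05450e-01,1.38419e-02,1.48081e-01,1.25331e-01
101,1.02205e-01,1.35700e-02,1.47738e-01,1.22206e-01
102,9.90901e-02,1.33056e-02,1.47398e-01,1.19209e-01
103,9.60979e-02,1.30485e-02,1.47059e-01,1.16333e-01
104,9.32227e-02,1.27984e-02,1.46723e-01,1.13572e-01
105,9.04591e-02,1.25550e-02,1.46389e-01,1.10920e-01
106,8.78016e-02,1.23179e-02,1.46057e-01,1.08373e-01
107,8.52453e-02,1.20871e-02,1.45727e-01,1.05924e-01
108,8.27855e-02,1.18623e-02,1.45400e-01,1.03571e-01
109,8.04176e-02,1.16431e-02,1.45074e-01,1.01307e-01
110,7.81376e-02,1.14294e-02,1.44751e-01,9.91302e-02
111,7.59414e-02,1.12211e-02,1.44429e-01,9.70350e-02
112,7.38251e-02,1.10178e-02,1.44110e-01,9.50183e-02
113,7.17853e-02,1.08195e-02,1.43793e-01,9.30765e-02
114,6.98186e-02,1.06259e-02,1.43478e-01,9.12061e-02
115,6.79217e-02,1.04369e-02,1.43164e-01,8.94042e-02
116,6.60916e-02,1.02523e-02,1.42853e-01,8.76676e-02
117,6.43254e-02,1.00719e-02,1.42544e-01,8.59935e-02
118,6.26205e-02,9.89562e-03,1.42236e-01,8.43793e-02
119,6.09741e-02,9.72331e-03,1.41931e-01,8.28223e-02
120,5.93838e-02,9.55484e-03,1.41627e-01,8.13201e-02
121,5.78472e-02,9.39006e-03,1.41325e-01,7.98705e-02
122,5.63623e-02,9.22887e-03,1.41025e-01,7.84711e-02
123,5.49267e-02,9.07113e-03,1.40727e-01,7.71200e-02
124,5.35385e-02,8.91675e-03,1.40431e-01,7.58151e-02
125,5.21958e-02,8.76561e-03,1.40137e-01,7.45545e-02
126,5.08968e-02,8.61760e-03,1.39844e-01,7.33365e-02
127,4.96396e-02,8.47265e-03,1.39553e-01,7.21592e-02
128,4.84228e-02,8.33064e-03,1.39264e-01,7.10212e-02
129,4.72446e-02,8.19149e-03,1.38976e-01,6.99208e-02
130,4.61035e-02,8.05511e-03,1.38691e-01,6.88565e-02
131,4.49982e-02,7.92143e-03,1.38407e-01,6.78269e-02
132,4.39272e-02,7.79036e-03,1.38124e-01,6.68307e-02
133,4.28893e-02,7.66183e-03,1.37844e-01,6.58666e-02
134,4.18832e-02,7.53577e-03,1.37565e-01,6.49334e-02
135,4.09077e-02,7.41210e-03,1.37287e-01,6.40298e-02
136,3.99616e-02,7.29077e-03,1.37011e-01,6.31548e-02
137,3.90439e-02,7.17171e-03,1.36737e-01,6.23072e-02
138,3.81535e-02,7.05485e-03,1.36465e-01,6.14861e-02
139,3.72894e-02,6.94015e-03,1.36194e-01,6.06905e-02
140,3.64507e-02,6.82753e-03,1.35924e-01,5.99194e-02
141,3.56365e-02,6.71696e-03,1.35656e-01,5.91719e-02
142,3.48458e-02,6.60838e-03,1.35390e-01,5.84472e-02
143,3.40779e-02,6.50173e-03,1.35125e-01,5.77444e-02
144,3.33319e-02,6.39698e-03,1.34862e-01,5.70628e-02
145,3.26071e-02,6.29407e-03,1.34600e-01,5.64016e-02
146,3.19027e-02,6.19296e-03,1.34340e-01,5.57601e-02
147,3.12180e-02,6.09361e-03,1.34081e-01,5.51376e-02
148,3.05524e-02,5.99597e-03,1.33823e-01,5.45334e-02
149,2.99052e-02,5.90002e-03,1.33567e-01,5.39468e-02
150,2.92758e-02,5.80570e-03,1.33313e-01,5.33774e-02
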