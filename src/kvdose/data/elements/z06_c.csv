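# element C Z=6 A=12.011
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,1.89776e+01,4.35544e-01,1.96308e-01,1.89771e+01
6,1.06721e+01,3.38413e-01,1.95566e-01,1.06732e+01
7,6.54292e+00,2.68557e-01,1.94832e-01,6.54491e+00
8,4.27454e+00,2.17597e-01,1.94106e-01,4.27713e+00
9,2.93208e+00,1.79606e-01,1.93386e-01,2.93515e+00
10,2.09037e+00,1.50629e-01,1.92674e-01,2.09385e+00
11,1.53772e+00,1.28057e-01,1.91968e-01,1.54158e+00
12,1.16092e+00,1.10143e-01,1.91269e-01,1.16513e+00
13,8.95813e-01,9.56929e-02,1.90576e-01,9.00362e-01
14,7.04262e-01,8.38725e-02,1.89891e-01,7.09138e-01
15,5.62666e-01,7.40835e-02,1.89212e-01,5.67860e-01
16,4.55906e-01,6.58889e-02,1.88539e-01,4.61413e-01
17,3.74006e-01,5.89628e-02,1.87872e-01,3.79818e-01
18,3.10209e-01,5.30586e-02,1.87212e-01,3.16321e-01
19,2.59833e-01,4.79865e-02,1.86558e-01,2.66238e-01
20,2.19566e-01,4.35985e-02,1.85910e-01,2.26261e-01
21,1.87026e-01,3.97782e-02,1.85268e-01,1.94005e-01
22,1.60466e-01,3.64325e-02,1.84632e-01,1.67726e-01
23,1.38591e-01,3.34869e-02,1.84001e-01,1.46127e-01
24,1.20425e-01,3.08804e-02,1.83377e-01,1.28232e-01
25,1.05224e-01,2.85636e-02,1.82758e-01,1.13299e-01
26,9.24161e-02,2.64953e-02,1.82144e-01,1.00754e-01
27,8.15538e-02,2.46415e-02,1.81536e-01,9.01511e-02
28,7.22866e-02,2.29739e-02,1.80934e-01,8.11394e-02
29,6.43363e-02,2.14684e-02,1.80337e-01,7.34408e-02
30,5.74804e-02,2.01050e-02,1.79745e-01,6.68329e-02
31,5.15396e-02,1.88664e-02,1.79158e-01,6.11365e-02
32,4.63685e-02,1.77380e-02,1.78577e-01,5.62062e-02
33,4.18482e-02,1.67071e-02,1.78000e-01,5.19232e-02
34,3.78810e-02,1.57630e-02,1.77429e-01,4.81899e-02
35,3.43861e-02,1.48962e-02,1.76863e-01,4.49256e-02
36,3.12965e-02,1.40985e-02,1.76301e-01,4.20632e-02
37,2.85558e-02,1.33630e-02,1.75744e-01,3.95466e-02
38,2.61171e-02,1.26832e-02,1.75192e-01,3.73286e-02
39,2.39404e-02,1.20538e-02,1.74645e-01,3.53697e-02
40,2.19922e-02,1.14700e-02,1.74103e-01,3.36361e-02
41,2.02437e-02,1.09274e-02,1.73565e-01,3.20992e-02
42,1.86703e-02,1.04224e-02,1.73031e-01,3.07345e-02
43,1.72511e-02,9.95159e-03,1.72502e-01,2.95210e-02
44,1.59679e-02,9.51192e-03,1.71977e-01,2.84407e-02
45,1.48051e-02,9.10076e-03,1.71457e-01,2.74780e-02
46,1.37492e-02,8.71571e-03,1.70941e-01,2.66194e-02
47,1.27883e-02,8.35463e-03,1.70429e-01,2.58532e-02
48,1.19122e-02,8.01557e-03,1.69922e-01,2.51690e-02
49,1.11119e-02,7.69680e-03,1.69418e-01,2.45580e-02
50,1.03795e-02,7.39672e-03,1.68919e-01,2.40124e-02
51,9.70808e-03,7.11390e-03,1.68424e-01,2.35253e-02
52,9.09157e-03,6.84705e-03,1.67932e-01,2.30905e-02
53,8.52455e-03,6.59498e-03,1.67445e-01,2.27028e-02
54,8.00224e-03,6.35661e-03,1.66961e-01,2.23574e-02
55,7.52040e-03,6.13095e-03,1.66482e-01,2.20501e-02
56,7.07526e-03,5.91711e-03,1.66006e-01,2.17771e-02
57,6.66345e-03,5.71426e-03,1.65534e-01,2.15352e-02
58,6.28197e-03,5.52164e-03,1.65065e-01,2.13214e-02
59,5.92812e-03,5.33855e-03,1.64601e-01,2.11330e-02
60,5.59951e-03,5.16435e-03,1.64140e-01,2.09677e-02
61,5.29395e-03,4.99846e-03,1.63682e-01,2.08233e-02
62,5.00951e-03,4.84034e-03,1.63228e-01,2.06979e-02
63,4.74442e-03,4.68947e-03,1.62777e-01,2.05898e-02
64,4.49709e-03,4.54540e-03,1.62330e-01,2.04974e-02
65,4.26609e-03,4.40770e-03,1.61887e-01,2.04193e-02
66,4.05013e-03,4.27597e-03,1.61446e-01,2.03543e-02
67,3.84802e-03,4.14985e-03,1.61010e-01,2.03012e-02
68,3.65868e-03,4.02900e-03,1.60576e-01,2.02590e-02
69,3.48115e-03,3.91310e-03,1.60145e-01,2.02266e-02
70,3.31454e-03,3.80185e-03,1.59718e-01,2.02034e-02
71,3.15804e-03,3.69499e-03,1.59294e-01,2.01885e-02
72,3.01090e-03,3.59227e-03,1.58873e-01,2.01811e-02
73,2.87245e-03,3.49345e-03,1.58456e-01,2.01806e-02
74,2.74208e-03,3.39831e-03,1.58041e-01,2.01865e-02
75,2.61921e-03,3.30665e-03,1.57629e-01,2.01982e-02
76,2.50332e-03,3.21828e-03,1.57221e-01,2.02152e-02
77,2.39393e-03,3.13302e-03,1.56815e-01,2.02370e-02
78,2.29060e-03,3.05072e-03,1.56412e-01,2.02632e-02
79,2.19294e-03,2.97121e-03,1.56013e-01,2.02935e-02
80,2.10055e-03,2.89436e-03,1.55616e-01,2.03275e-02
81,2.01310e-03,2.82003e-03,1.55222e-01,2.03649e-02
82,1.93027e-03,2.74810e-03,1.54830e-01,2.04054e-02
83,1.85176e-03,2.67845e-03,1.54442e-01,2.04487e-02
84,1.77731e-03,2.61098e-03,1.54056e-01,2.04945e-02
85,1.70665e-03,2.54558e-03,1.53673e-01,2.05427e-02
86,1.63956e-03,2.48215e-03,1.53293e-01,2.05930e-02
87,1.57581e-03,2.42062e-03,1.52915e-01,2.06452e-02
88,1.51521e-03,2.36089e-03,1.52540e-01,2.06992e-02
89,1.45757e-03,2.30290e-03,1.52167e-01,2.07548e-02
90,1.40271e-03,2.24656e-03,1.51797e-01,2.08117e-02
91,1.35047e-03,2.19180e-03,1.51430e-01,2.08700e-02
92,1.30071e-03,2.13857e-03,1.51065e-01,2.09294e-02
93,1.25326e-03,2.08680e-03,1.50703e-01,2.09898e-02
94,1.20802e-03,2.03644e-03,1.50343e-01,2.10512e-02
95,1.16485e-03,1.98743e-03,1.49986e-01,2.11133e-02
96,1.12364e-03,1.93973e-03,1.49631e-01,2.11762e-02
97,1.08428e-03,1.89327e-03,1.49278e-01,2.12397e-02
98,1.04667e-03,1.84803e-03,1.48928e-01,2.13037e-02
99,1.01071e-03,1.80396e-03,1.48580e-01,2.13682e-02
100,9.76327e-04,1.76101e-03,1.48234e-01,2.14331e-02
101,9.43426e-04,1.71915e-03,1.47891e-01,2.14984e-02
102,9.11934e-04,1.67835e-03,1.47550e-01,2.15639e-02
103,8.81776e-04,1.63856e-03,1.47211e-01,2.16296e-02
104,8.52885e-04,1.59977e-03,1.46874e-01,2.16954e-02
105,8.25196e-04,1.56193e-03,1.46540e-01,2.17614e-02
106,7.98649e-04,1.52502e-03,1.46208e-01,2.18274e-02
107,7.73186e-04,1.48901e-03,1.45878e-01,2.18935e-02
108,7.48755e-04,1.45387e-03,1.45550e-01,2.19595e-02
109,7.25304e-04,1.41958e-03,1.45224e-01,2.20255e-02
110,7.02785e-04,1.38612e-03,1.44900e-01,2.20914e-02
111,6.81155e-04,1.35345e-03,1.44579e-01,2.21572e-02
112,6.60370e-04,1.32157e-03,1.44259e-01,2.22229e-02
113,6.40391e-04,1.29045e-03,1.43941e-01,2.22883e-02
114,6.21180e-04,1.26006e-03,1.43626e-01,2.23536e-02
115,6.02700e-04,1.23039e-03,1.43312e-01,2.24187e-02
116,5.84919e-04,1.20142e-03,1.43001e-01,2.24835e-02
117,5.67805e-04,1.17314e-03,1.42691e-01,2.25481e-02
118,5.51326e-04,1.14551e-03,1.42383e-01,2.26124e-02
119,5.35455e-04,1.11854e-03,1.42077e-01,2.26763e-02
120,5.20165e-04,1.09220e-03,1.41773e-01,2.27400e-02
121,5.05429e-04,1.06647e-03,1.41471e-01,2.28034e-02
122,4.91223e-04,1.04135e-03,1.41171e-01,2.28664e-02
123,4.77525e-04,1.01681e-03,1.40873e-01,2.29291e-02
124,4.64312e-04,9.92842e-04,1.40576e-01,2.29915e-02
125,4.51563e-04,9.69435e-04,1.40281e-01,2.30534e-02
126,4.39259e-04,9.46573e-04,1.39988e-01,2.31150e-02
127,4.27381e-04,9.24245e-04,1.39697e-01,2.31762e-02
128,4.15911e-04,9.02436e-04,1.39408e-01,2.32371e-02
129,4.04833e-04,8.81136e-04,1.39120e-01,2.32975e-02
130,3.94129e-04,8.60332e-04,1.38834e-01,2.33575e-02
131,3.83784e-04,8.40012e-04,1.38550e-01,2.34171e-02
132,3.73785e-04,8.20167e-04,1.38267e-01,2.34763e-02
133,3.64117e-04,8.00784e-04,1.37986e-01,2.35351e-02
134,3.54766e-04,7.81854e-04,1.37707e-01,2.35935e-02
135,3.45721e-04,7.63365e-04,1.37429e-01,2.36514e-02
136,3.36968e-04,7.45309e-04,1.37153e-01,2.37090e-02
137,3.28497e-04,7.27674e-04,1.36878e-01,2.37661e-02
138,3.20297e-04,7.10452e-04,1.36606e-01,2.38227e-02
139,3.12356e-04,6.93633e-04,1.36334e-01,2.38790e-02
140,3.04666e-04,6.77208e-04,1.36065e-01,2.39348e-02
141,2.97217e-04,6.61168e-04,1.35796e-01,2.39901e-02
142,2.89999e-04,6.45505e-04,1.35530e-01,2.40451e-02
143,2.83003e-04,6.30209e-04,1.35265e-01,2.40996e-02
144,2.76222e-04,6.15273e-04,1.35001e-01,2.41536e-02
145,2.69648e-04,6.00688e-04,1.34739e-01,2.42073e-02
146,2.63272e-04,5.86447e-04,1.34478e-01,2.42605e-02
147,2.57088e-04,5.72541e-04,1.34219e-01,2.43133e-02
148,2.51088e-04,5.58963e-04,1.33962e-01,2.43656e-02
149,2.45267e-04,5.45706e-04,1.33705e-01,2.44175e-02
150,2.39616e-04,5.32762e-04,1.33450e-01,2.44690e-02
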