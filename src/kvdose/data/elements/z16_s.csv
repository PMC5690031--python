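# element S Z=16 A=32.06
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,4.09739e+02,1.69016e+00,1.96120e-01,3.97100e+02
6,2.41062e+02,1.38875e+00,1.95379e-01,2.34867e+02
7,1.53544e+02,1.14590e+00,1.94646e-01,1.50163e+02
8,1.03685e+02,9.53953e-01,1.93920e-01,1.01688e+02
9,7.32269e+01,8.02818e-01,1.93201e-01,7.19751e+01
10,5.35861e+01,6.83218e-01,1.92489e-01,5.27631e+01
11,4.03608e+01,5.87651e-01,1.91784e-01,3.97988e+01
12,3.11347e+01,5.10397e-01,1.91086e-01,3.07388e+01
13,2.45058e+01,4.47193e-01,1.90394e-01,2.42197e+01
14,1.96227e+01,3.94885e-01,1.89709e-01,1.94114e+01
15,1.59476e+01,3.51129e-01,1.89031e-01,1.57889e+01
16,1.31300e+01,3.14170e-01,1.88358e-01,1.30089e+01
17,1.09342e+01,2.82675e-01,1.87693e-01,1.08409e+01
18,9.19842e+00,2.55623e-01,1.87033e-01,9.12571e+00
19,7.80852e+00,2.32221e-01,1.86379e-01,7.75153e+00
20,6.68279e+00,2.11843e-01,1.85732e-01,6.63795e+00
21,5.76158e+00,1.93993e-01,1.85091e-01,5.72624e+00
22,5.00066e+00,1.78274e-01,1.84455e-01,4.97286e+00
23,4.36678e+00,1.64361e-01,1.83825e-01,4.34503e+00
24,3.83461e+00,1.51991e-01,1.83201e-01,3.81777e+00
25,3.38464e+00,1.40946e-01,1.82583e-01,3.37183e+00
26,3.00167e+00,1.31045e-01,1.81970e-01,2.99220e+00
27,2.67374e+00,1.22136e-01,1.81363e-01,2.66706e+00
28,2.39136e+00,1.14094e-01,1.80761e-01,2.38703e+00
29,2.14693e+00,1.06809e-01,1.80164e-01,2.14461e+00
30,1.93432e+00,1.00192e-01,1.79573e-01,1.93372e+00
31,1.74855e+00,9.41628e-02,1.78987e-01,1.74944e+00
32,1.58553e+00,8.86553e-02,1.78406e-01,1.58772e+00
33,1.44191e+00,8.36116e-02,1.77830e-01,1.44524e+00
34,1.31491e+00,7.89813e-02,1.77259e-01,1.31924e+00
35,1.20219e+00,7.47211e-02,1.76693e-01,1.20743e+00
36,1.10184e+00,7.07927e-02,1.76132e-01,1.10787e+00
37,1.01219e+00,6.71630e-02,1.75576e-01,1.01895e+00
38,9.31885e-01,6.38027e-02,1.75025e-01,9.39304e-01
39,8.59734e-01,6.06860e-02,1.74478e-01,8.67753e-01
40,7.94739e-01,5.77901e-02,1.73936e-01,8.03307e-01
41,7.36040e-01,5.50948e-02,1.73398e-01,7.45115e-01
42,6.82898e-01,5.25821e-02,1.72865e-01,6.92442e-01
43,6.34676e-01,5.02361e-02,1.72337e-01,6.44657e-01
44,5.90821e-01,4.80424e-02,1.71813e-01,6.01211e-01
45,5.50855e-01,4.59882e-02,1.71293e-01,5.61628e-01
46,5.14359e-01,4.40621e-02,1.70777e-01,5.25493e-01
47,4.80967e-01,4.22537e-02,1.70266e-01,4.92441e-01
48,4.50360e-01,4.05536e-02,1.69759e-01,4.62157e-01
49,4.22254e-01,3.89535e-02,1.69256e-01,4.34358e-01
50,3.96401e-01,3.74457e-02,1.68757e-01,4.08798e-01
51,3.72583e-01,3.60233e-02,1.68262e-01,3.85260e-01
52,3.50605e-01,3.46801e-02,1.67772e-01,3.63550e-01
53,3.30293e-01,3.34103e-02,1.67285e-01,3.43496e-01
54,3.11494e-01,3.22086e-02,1.66802e-01,3.24946e-01
55,2.94072e-01,3.10705e-02,1.66322e-01,3.07763e-01
56,2.77903e-01,2.99914e-02,1.65847e-01,2.91825e-01
57,2.62878e-01,2.89674e-02,1.65375e-01,2.77024e-01
58,2.48898e-01,2.79949e-02,1.64907e-01,2.63261e-01
59,2.35875e-01,2.70705e-02,1.64443e-01,2.50449e-01
60,2.23729e-01,2.61910e-02,1.63983e-01,2.38507e-01
61,2.12388e-01,2.53538e-02,1.63525e-01,2.27366e-01
62,2.01788e-01,2.45560e-02,1.63072e-01,2.16959e-01
63,1.91868e-01,2.37953e-02,1.62622e-01,2.07229e-01
64,1.82577e-01,2.30695e-02,1.62175e-01,1.98122e-01
65,1.73865e-01,2.23764e-02,1.61732e-01,1.89591e-01
66,1.65689e-01,2.17142e-02,1.61292e-01,1.81590e-01
67,1.58008e-01,2.10810e-02,1.60856e-01,1.74082e-01
68,1.50786e-01,2.04751e-02,1.60422e-01,1.67028e-01
69,1.43989e-01,1.98951e-02,1.59992e-01,1.60397e-01
70,1.37587e-01,1.93395e-02,1.59566e-01,1.54157e-01
71,1.31552e-01,1.88069e-02,1.59142e-01,1.48280e-01
72,1.25858e-01,1.82960e-02,1.58721e-01,1.42742e-01
73,1.20482e-01,1.78058e-02,1.58304e-01,1.37519e-01
74,1.15402e-01,1.73350e-02,1.57890e-01,1.32589e-01
75,1.10598e-01,1.68828e-02,1.57479e-01,1.27932e-01
76,1.06052e-01,1.64480e-02,1.57070e-01,1.23531e-01
77,1.01746e-01,1.60298e-02,1.56665e-01,1.19369e-01
78,9.76665e-02,1.56273e-02,1.56263e-01,1.15429e-01
79,9.37976e-02,1.52399e-02,1.55863e-01,1.11698e-01
80,9.01263e-02,1.48666e-02,1.55467e-01,1.08162e-01
81,8.66404e-02,1.45068e-02,1.55073e-01,1.04810e-01
82,8.33284e-02,1.41598e-02,1.54682e-01,1.01629e-01
83,8.01797e-02,1.38251e-02,1.54294e-01,9.86099e-02
84,7.71845e-02,1.35019e-02,1.53909e-01,9.57421e-02
85,7.43336e-02,1.31899e-02,1.53526e-01,9.30168e-02
86,7.16186e-02,1.28883e-02,1.53146e-01,9.04255e-02
87,6.90315e-02,1.25969e-02,1.52769e-01,8.79603e-02
88,6.65649e-02,1.23150e-02,1.52394e-01,8.56139e-02
89,6.42121e-02,1.20422e-02,1.52022e-01,8.33796e-02
90,6.19666e-02,1.17781e-02,1.51652e-01,8.12509e-02
91,5.98224e-02,1.15224e-02,1.51285e-01,7.92219e-02
92,5.77740e-02,1.12746e-02,1.50921e-01,7.72870e-02
93,5.58160e-02,1.10345e-02,1.50559e-01,7.54411e-02
94,5.39437e-02,1.08016e-02,1.50199e-01,7.36794e-02
95,5.21525e-02,1.05756e-02,1.49842e-01,7.19972e-02
96,5.04380e-02,1.03563e-02,1.49487e-01,7.03903e-02
97,4.87962e-02,1.01434e-02,1.49135e-01,6.88548e-02
98,4.72235e-02,9.93652e-03,1.48785e-01,6.73868e-02
99,4.57161e-02,9.73552e-03,1.48438e-01,6.59829e-02
100,4.42709e-02,9.54011e-03,1.48092e-01,6.46398e-02
101,4.28846e-02,9.35007e-03,1.47749e-01,6.33544e-02
102,4.15544e-02,9.16517e-03,1.47409e-01,6.21237e-02
103,4.02774e-02,8.98522e-03,1.47070e-01,6.09450e-02
104,3.90510e-02,8.81002e-03,1.46734e-01,5.98157e-02
105,3.78729e-02,8.63937e-03,1.46400e-01,5.87335e-02
106,3.67407e-02,8.47311e-03,1.46068e-01,5.76959e-02
107,3.56521e-02,8.31105e-03,1.45738e-01,5.67008e-02
108,3.46052e-02,8.15305e-03,1.45411e-01,5.57463e-02
109,3.35980e-02,7.99895e-03,1.45085e-01,5.48303e-02
110,3.26286e-02,7.84861e-03,1.44762e-01,5.39510e-02
111,3.16953e-02,7.70188e-03,1.44440e-01,5.31068e-02
112,3.07965e-02,7.55864e-03,1.44121e-01,5.22960e-02
113,2.99306e-02,7.41876e-03,1.43804e-01,5.15170e-02
114,2.90961e-02,7.28212e-03,1.43488e-01,5.07684e-02
115,2.82917e-02,7.14862e-03,1.43175e-01,5.00489e-02
116,2.75160e-02,7.01813e-03,1.42864e-01,4.93570e-02
117,2.67677e-02,6.89057e-03,1.42554e-01,4.86917e-02
118,2.60457e-02,6.76582e-03,1.42247e-01,4.80516e-02
119,2.53489e-02,6.64381e-03,1.41941e-01,4.74357e-02
120,2.46761e-02,6.52443e-03,1.41638e-01,4.68430e-02
121,2.40264e-02,6.40761e-03,1.41336e-01,4.62724e-02
122,2.33987e-02,6.29327e-03,1.41036e-01,4.57230e-02
123,2.27923e-02,6.18132e-03,1.40738e-01,4.51938e-02
124,2.22061e-02,6.07170e-03,1.40442e-01,4.46841e-02
125,2.16394e-02,5.96433e-03,1.40147e-01,4.41929e-02
126,2.10914e-02,5.85914e-03,1.39854e-01,4.37196e-02
127,2.05613e-02,5.75608e-03,1.39563e-01,4.32634e-02
128,2.00484e-02,5.65508e-03,1.39274e-01,4.28235e-02
129,1.95520e-02,5.55608e-03,1.38987e-01,4.23993e-02
130,1.90715e-02,5.45902e-03,1.38701e-01,4.19902e-02
131,1.86062e-02,5.36386e-03,1.38417e-01,4.15956e-02
132,1.81556e-02,5.27054e-03,1.38135e-01,4.12148e-02
133,1.77191e-02,5.17901e-03,1.37854e-01,4.08473e-02
134,1.72961e-02,5.08922e-03,1.37575e-01,4.04927e-02
135,1.68862e-02,5.00113e-03,1.37298e-01,4.01503e-02
136,1.64888e-02,4.91470e-03,1.37022e-01,3.98197e-02
137,1.61035e-02,4.82988e-03,1.36748e-01,3.95005e-02
138,1.57298e-02,4.74663e-03,1.36475e-01,3.91921e-02
139,1.53673e-02,4.66492e-03,1.36204e-01,3.88943e-02
140,1.50156e-02,4.58470e-03,1.35934e-01,3.86065e-02
141,1.46743e-02,4.50595e-03,1.35667e-01,3.83285e-02
142,1.43430e-02,4.42862e-03,1.35400e-01,3.80598e-02
143,1.40214e-02,4.35269e-03,1.35135e-01,3.78000e-02
144,1.37090e-02,4.27813e-03,1.34872e-01,3.75489e-02
145,1.34057e-02,4.20489e-03,1.34610e-01,3.73062e-02
146,1.31110e-02,4.13296e-03,1.34350e-01,3.70714e-02
147,1.28247e-02,4.06230e-03,1.34091e-01,3.68444e-02
148,1.25465e-02,3.99289e-03,1.33833e-01,3.66248e-02
149,1.22760e-02,3.92470e-03,1.33577e-01,3.64124e-02
150,1.20131e-02,3.85771e-03,1.33323e-01,3.62070e-02
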