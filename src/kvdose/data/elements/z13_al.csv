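# element Al Z=13 A=26.982
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,2.06382e+02,1.23560e+00,1.89336e-01,2.04374e+02
6,1.20265e+02,1.00205e+00,1.88622e-01,1.19292e+02
7,7.59860e+01,8.18813e-01,1.87914e-01,7.54602e+01
8,5.09535e+01,6.76892e-01,1.87213e-01,5.06464e+01
9,3.57642e+01,5.66789e-01,1.86519e-01,3.55740e+01
10,2.60274e+01,4.80564e-01,1.85831e-01,2.59042e+01
11,1.95060e+01,4.12165e-01,1.85151e-01,1.94235e+01
12,1.49786e+01,3.57155e-01,1.84477e-01,1.49220e+01
13,1.17402e+01,3.12320e-01,1.83809e-01,1.17006e+01
14,9.36429e+00,2.75321e-01,1.83147e-01,9.33647e+00
15,7.58301e+00,2.44444e-01,1.82492e-01,7.56344e+00
16,6.22214e+00,2.18417e-01,1.81843e-01,6.20854e+00
17,5.16516e+00,1.96278e-01,1.81201e-01,5.15599e+00
18,4.33218e+00,1.77293e-01,1.80564e-01,4.32637e+00
19,3.66717e+00,1.60895e-01,1.79933e-01,3.66396e+00
20,3.13005e+00,1.46636e-01,1.79308e-01,3.12890e+00
21,2.69169e+00,1.34164e-01,1.78689e-01,2.69219e+00
22,2.33051e+00,1.23194e-01,1.78075e-01,2.33236e+00
23,2.03036e+00,1.13496e-01,1.77467e-01,2.03333e+00
24,1.77895e+00,1.04883e-01,1.76865e-01,1.78287e+00
25,1.56684e+00,9.72006e-02,1.76268e-01,1.57158e+00
26,1.38670e+00,9.03206e-02,1.75676e-01,1.39215e+00
27,1.23276e+00,8.41361e-02,1.75090e-01,1.23883e+00
28,1.10047e+00,7.85574e-02,1.74509e-01,1.10709e+00
29,9.86168e-01,7.35088e-02,1.73933e-01,9.93295e-01
30,8.86930e-01,6.89257e-02,1.73362e-01,8.94513e-01
31,8.00371e-01,6.47531e-02,1.72796e-01,8.08372e-01
32,7.24545e-01,6.09441e-02,1.72235e-01,7.32932e-01
33,6.57852e-01,5.74578e-02,1.71679e-01,6.66600e-01
34,5.98969e-01,5.42592e-02,1.71128e-01,6.08056e-01
35,5.46795e-01,5.13177e-02,1.70582e-01,5.56201e-01
36,5.00409e-01,4.86068e-02,1.70040e-01,5.10118e-01
37,4.59038e-01,4.61032e-02,1.69503e-01,4.69035e-01
38,4.22026e-01,4.37864e-02,1.68971e-01,4.32300e-01
39,3.88821e-01,4.16384e-02,1.68443e-01,3.99360e-01
40,3.58950e-01,3.96434e-02,1.67920e-01,3.69744e-01
41,3.32007e-01,3.77873e-02,1.67401e-01,3.43048e-01
42,3.07648e-01,3.60576e-02,1.66886e-01,3.18927e-01
43,2.85571e-01,3.44431e-02,1.66376e-01,2.97082e-01
44,2.65519e-01,3.29340e-02,1.65870e-01,2.77255e-01
45,2.47266e-01,3.15212e-02,1.65368e-01,2.59222e-01
46,2.30618e-01,3.01970e-02,1.64871e-01,2.42787e-01
47,2.15403e-01,2.89540e-02,1.64377e-01,2.27781e-01
48,2.01473e-01,2.77857e-02,1.63887e-01,2.14055e-01
49,1.88695e-01,2.66865e-02,1.63402e-01,2.01477e-01
50,1.76955e-01,2.56509e-02,1.62920e-01,1.89932e-01
51,1.66150e-01,2.46743e-02,1.62443e-01,1.79318e-01
52,1.56189e-01,2.37522e-02,1.61969e-01,1.69545e-01
53,1.46994e-01,2.28807e-02,1.61499e-01,1.60534e-01
54,1.38492e-01,2.20562e-02,1.61032e-01,1.52213e-01
55,1.30620e-01,2.12754e-02,1.60570e-01,1.44518e-01
56,1.23322e-01,2.05353e-02,1.60111e-01,1.37394e-01
57,1.16546e-01,1.98331e-02,1.59655e-01,1.30790e-01
58,1.10247e-01,1.91664e-02,1.59204e-01,1.24660e-01
59,1.04385e-01,1.85327e-02,1.58755e-01,1.18964e-01
60,9.89231e-02,1.79300e-02,1.58311e-01,1.13665e-01
61,9.38274e-02,1.73563e-02,1.57869e-01,1.08730e-01
62,8.90684e-02,1.68097e-02,1.57432e-01,1.04130e-01
63,8.46190e-02,1.62886e-02,1.56997e-01,9.98363e-02
64,8.04548e-02,1.57914e-02,1.56566e-01,9.58258e-02
65,7.65536e-02,1.53167e-02,1.56138e-01,9.20759e-02
66,7.28952e-02,1.48632e-02,1.55713e-01,8.85667e-02
67,6.94612e-02,1.44296e-02,1.55292e-01,8.52796e-02
68,6.62348e-02,1.40147e-02,1.54874e-01,8.21982e-02
69,6.32008e-02,1.36175e-02,1.54459e-01,7.93071e-02
70,6.03453e-02,1.32370e-02,1.54046e-01,7.65925e-02
71,5.76554e-02,1.28723e-02,1.53638e-01,7.40415e-02
72,5.51195e-02,1.25224e-02,1.53232e-01,7.16427e-02
73,5.27268e-02,1.21867e-02,1.52829e-01,6.93852e-02
74,5.04675e-02,1.18642e-02,1.52429e-01,6.72593e-02
75,4.83326e-02,1.15543e-02,1.52032e-01,6.52560e-02
76,4.63137e-02,1.12563e-02,1.51638e-01,6.33669e-02
77,4.44031e-02,1.09697e-02,1.51246e-01,6.15845e-02
78,4.25938e-02,1.06938e-02,1.50858e-01,5.99016e-02
79,4.08792e-02,1.04280e-02,1.50472e-01,5.83119e-02
80,3.92533e-02,1.01719e-02,1.50090e-01,5.68091e-02
81,3.77105e-02,9.92496e-03,1.49709e-01,5.53880e-02
82,3.62456e-02,9.68673e-03,1.49332e-01,5.40431e-02
83,3.48538e-02,9.45678e-03,1.48957e-01,5.27699e-02
84,3.35307e-02,9.23470e-03,1.48585e-01,5.15639e-02
85,3.22722e-02,9.02012e-03,1.48216e-01,5.04209e-02
86,3.10744e-02,8.81267e-03,1.47849e-01,4.93372e-02
87,2.99337e-02,8.61201e-03,1.47485e-01,4.83093e-02
88,2.88469e-02,8.41784e-03,1.47123e-01,4.73337e-02
89,2.78108e-02,8.22984e-03,1.46764e-01,4.64075e-02
90,2.68225e-02,8.04773e-03,1.46407e-01,4.55278e-02
91,2.58794e-02,7.87124e-03,1.46053e-01,4.46919e-02
92,2.49789e-02,7.70012e-03,1.45701e-01,4.38973e-02
93,2.41187e-02,7.53414e-03,1.45351e-01,4.31418e-02
94,2.32966e-02,7.37305e-03,1.45004e-01,4.24230e-02
95,2.25105e-02,7.21666e-03,1.44659e-01,4.17391e-02
96,2.17586e-02,7.06475e-03,1.44317e-01,4.10880e-02
97,2.10389e-02,6.91714e-03,1.43977e-01,4.04680e-02
98,2.03498e-02,6.77365e-03,1.43639e-01,3.98774e-02
99,1.96898e-02,6.63409e-03,1.43304e-01,3.93147e-02
100,1.90573e-02,6.49832e-03,1.42970e-01,3.87784e-02
101,1.84509e-02,6.36618e-03,1.42639e-01,3.82670e-02
102,1.78693e-02,6.23752e-03,1.42310e-01,3.77793e-02
103,1.73113e-02,6.11220e-03,1.41983e-01,3.73142e-02
104,1.67758e-02,5.99009e-03,1.41659e-01,3.68703e-02
105,1.62615e-02,5.87108e-03,1.41336e-01,3.64467e-02
106,1.57675e-02,5.75503e-03,1.41016e-01,3.60423e-02
107,1.52928e-02,5.64185e-03,1.40697e-01,3.56561e-02
108,1.48365e-02,5.53142e-03,1.40381e-01,3.52874e-02
109,1.43977e-02,5.42364e-03,1.40067e-01,3.49351e-02
110,1.39756e-02,5.31842e-03,1.39755e-01,3.45985e-02
111,1.35694e-02,5.21567e-03,1.39444e-01,3.42769e-02
112,1.31784e-02,5.11530e-03,1.39136e-01,3.39695e-02
113,1.28019e-02,5.01723e-03,1.38830e-01,3.36756e-02
114,1.24392e-02,4.92139e-03,1.38525e-01,3.33946e-02
115,1.20898e-02,4.82769e-03,1.38223e-01,3.31259e-02
116,1.17530e-02,4.73607e-03,1.37922e-01,3.28690e-02
117,1.14282e-02,4.64646e-03,1.37624e-01,3.26232e-02
118,1.11150e-02,4.55879e-03,1.37327e-01,3.23880e-02
119,1.08128e-02,4.47302e-03,1.37032e-01,3.21631e-02
120,1.05212e-02,4.38907e-03,1.36739e-01,3.19478e-02
121,1.02398e-02,4.30689e-03,1.36447e-01,3.17418e-02
122,9.96797e-03,4.22644e-03,1.36158e-01,3.15446e-02
123,9.70546e-03,4.14765e-03,1.35870e-01,3.13559e-02
124,9.45184e-03,4.07048e-03,1.35584e-01,3.11753e-02
125,9.20675e-03,3.99490e-03,1.35300e-01,3.10024e-02
126,8.96984e-03,3.92084e-03,1.35017e-01,3.08369e-02
127,8.74076e-03,3.84827e-03,1.34736e-01,3.06784e-02
128,8.51922e-03,3.77715e-03,1.34457e-01,3.05267e-02
129,8.30490e-03,3.70745e-03,1.34180e-01,3.03815e-02
130,8.09752e-03,3.63911e-03,1.33904e-01,3.02424e-02
131,7.89679e-03,3.57212e-03,1.33629e-01,3.01093e-02
132,7.70248e-03,3.50643e-03,1.33357e-01,2.99818e-02
133,7.51431e-03,3.44202e-03,1.33086e-01,2.98597e-02
134,7.33205e-03,3.37884e-03,1.32816e-01,2.97429e-02
135,7.15549e-03,3.31688e-03,1.32549e-01,2.96310e-02
136,6.98439e-03,3.25610e-03,1.32282e-01,2.95239e-02
137,6.81856e-03,3.19647e-03,1.32018e-01,2.94214e-02
138,6.65780e-03,3.13797e-03,1.31755e-01,2.93233e-02
139,6.50191e-03,3.08057e-03,1.31493e-01,2.92294e-02
140,6.35071e-03,3.02425e-03,1.31233e-01,2.91395e-02
141,6.20404e-03,2.96899e-03,1.30974e-01,2.90535e-02
142,6.06173e-03,2.91475e-03,1.30717e-01,2.89712e-02
143,5.92362e-03,2.86152e-03,1.30461e-01,2.88924e-02
144,5.78956e-03,2.80928e-03,1.30207e-01,2.88171e-02
145,5.65940e-03,2.75800e-03,1.29954e-01,2.87451e-02
146,5.53301e-03,2.70767e-03,1.29703e-01,2.86762e-02
147,5.41024e-03,2.65826e-03,1.29453e-01,2.86104e-02
148,5.29099e-03,2.60976e-03,1.29204e-01,2.85474e-02
149,5.17511e-03,2.56214e-03,1.28957e-01,2.84873e-02
150,5.06250e-03,2.51540e-03,1.28711e-01,2.84298e-02
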