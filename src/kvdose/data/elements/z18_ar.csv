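# element Ar Z=18 A=39.948
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,5.35062e+02,1.78262e+00,1.77069e-01,5.02676e+02
6,3.16505e+02,1.47585e+00,1.76400e-01,3.00542e+02
7,2.02523e+02,1.22489e+00,1.75738e-01,1.93770e+02
8,1.37304e+02,1.02410e+00,1.75083e-01,1.32112e+02
9,9.73105e+01,8.64559e-01,1.74434e-01,9.40412e+01
10,7.14336e+01,7.37463e-01,1.73791e-01,6.92750e+01
11,5.39562e+01,6.35428e-01,1.73154e-01,5.24753e+01
12,4.17302e+01,5.52667e-01,1.72524e-01,4.06816e+01
13,3.29237e+01,4.84792e-01,1.71900e-01,3.21614e+01
14,2.64214e+01,4.28514e-01,1.71281e-01,2.58546e+01
15,2.15171e+01,3.81369e-01,1.70668e-01,2.10877e+01
16,1.77495e+01,3.41498e-01,1.70061e-01,1.74187e+01
17,1.48079e+01,3.07486e-01,1.69460e-01,1.45495e+01
18,1.24783e+01,2.78244e-01,1.68865e-01,1.22740e+01
19,1.06099e+01,2.52924e-01,1.68275e-01,1.04467e+01
20,9.09415e+00,2.30859e-01,1.67690e-01,8.96258e+00
21,7.85193e+00,2.11516e-01,1.67111e-01,7.74507e+00
22,6.82438e+00,1.94469e-01,1.66537e-01,6.73705e+00
23,5.96721e+00,1.79371e-01,1.65969e-01,5.89549e+00
24,5.24664e+00,1.65938e-01,1.65405e-01,5.18752e+00
25,4.63660e+00,1.53937e-01,1.64847e-01,4.58776e+00
26,4.11677e+00,1.43172e-01,1.64294e-01,4.07637e+00
27,3.67114e+00,1.33482e-01,1.63745e-01,3.63774e+00
28,3.28697e+00,1.24729e-01,1.63202e-01,3.25943e+00
29,2.95408e+00,1.16798e-01,1.62663e-01,2.93147e+00
30,2.66423e+00,1.09589e-01,1.62129e-01,2.64579e+00
31,2.41070e+00,1.03018e-01,1.61600e-01,2.39582e+00
32,2.18802e+00,9.70141e-02,1.61076e-01,2.17620e+00
33,1.99164e+00,9.15134e-02,1.60556e-01,1.98247e+00
34,1.81783e+00,8.64619e-02,1.60041e-01,1.81095e+00
35,1.66344e+00,8.18125e-02,1.59530e-01,1.65857e+00
36,1.52586e+00,7.75240e-02,1.59023e-01,1.52274e+00
37,1.40286e+00,7.35604e-02,1.58521e-01,1.40130e+00
38,1.29258e+00,6.98900e-02,1.58023e-01,1.29240e+00
39,1.19343e+00,6.64848e-02,1.57530e-01,1.19447e+00
40,1.10403e+00,6.33202e-02,1.57040e-01,1.10618e+00
41,1.02324e+00,6.03740e-02,1.56555e-01,1.02638e+00
42,9.50045e-01,5.76269e-02,1.56074e-01,9.54081e-01
43,8.83577e-01,5.50615e-02,1.55596e-01,8.88426e-01
44,8.23087e-01,5.26622e-02,1.55123e-01,8.28676e-01
45,7.67922e-01,5.04151e-02,1.54654e-01,7.74189e-01
46,7.17514e-01,4.83077e-02,1.54188e-01,7.24402e-01
47,6.71363e-01,4.63287e-02,1.53727e-01,6.78824e-01
48,6.29032e-01,4.44681e-02,1.53269e-01,6.37024e-01
49,5.90137e-01,4.27165e-02,1.52815e-01,5.98621e-01
50,5.54340e-01,4.10658e-02,1.52364e-01,5.63281e-01
51,5.21338e-01,3.95083e-02,1.51918e-01,5.30708e-01
52,4.90868e-01,3.80373e-02,1.51474e-01,5.00638e-01
53,4.62693e-01,3.66465e-02,1.51035e-01,4.72839e-01
54,4.36601e-01,3.53302e-02,1.50599e-01,4.47103e-01
55,4.12406e-01,3.40833e-02,1.50166e-01,4.23243e-01
56,3.89940e-01,3.29010e-02,1.49737e-01,4.01094e-01
57,3.69052e-01,3.17789e-02,1.49311e-01,3.80506e-01
58,3.49606e-01,3.07131e-02,1.48889e-01,3.61348e-01
59,3.31482e-01,2.96998e-02,1.48469e-01,3.43497e-01
60,3.14571e-01,2.87358e-02,1.48053e-01,3.26846e-01
61,2.98772e-01,2.78179e-02,1.47641e-01,3.11297e-01
62,2.83997e-01,2.69432e-02,1.47231e-01,2.96762e-01
63,2.70165e-01,2.61091e-02,1.46825e-01,2.83160e-01
64,2.57203e-01,2.53131e-02,1.46422e-01,2.70419e-01
65,2.45043e-01,2.45531e-02,1.46021e-01,2.58473e-01
66,2.33626e-01,2.38267e-02,1.45624e-01,2.47261e-01
67,2.22895e-01,2.31322e-02,1.45230e-01,2.36729e-01
68,2.12801e-01,2.24676e-02,1.44839e-01,2.26827e-01
69,2.03297e-01,2.18313e-02,1.44451e-01,2.17510e-01
70,1.94341e-01,2.12218e-02,1.44066e-01,2.08735e-01
71,1.85895e-01,2.06375e-02,1.43683e-01,2.00464e-01
72,1.77923e-01,2.00771e-02,1.43303e-01,1.92663e-01
73,1.70393e-01,1.95392e-02,1.42927e-01,1.85298e-01
74,1.63274e-01,1.90228e-02,1.42553e-01,1.78341e-01
75,1.56540e-01,1.85266e-02,1.42181e-01,1.71764e-01
76,1.50164e-01,1.80496e-02,1.41813e-01,1.65542e-01
77,1.44124e-01,1.75909e-02,1.41447e-01,1.59652e-01
78,1.38398e-01,1.71495e-02,1.41084e-01,1.54073e-01
79,1.32966e-01,1.67245e-02,1.40723e-01,1.48784e-01
80,1.27810e-01,1.63151e-02,1.40365e-01,1.43767e-01
81,1.22912e-01,1.59206e-02,1.40009e-01,1.39006e-01
82,1.18256e-01,1.55402e-02,1.39657e-01,1.34484e-01
83,1.13829e-01,1.51733e-02,1.39306e-01,1.30188e-01
84,1.09616e-01,1.48191e-02,1.38958e-01,1.26104e-01
85,1.05604e-01,1.44772e-02,1.38613e-01,1.22218e-01
86,1.01782e-01,1.41468e-02,1.38270e-01,1.18520e-01
87,9.81393e-02,1.38276e-02,1.37929e-01,1.14998e-01
88,9.46649e-02,1.35189e-02,1.37591e-01,1.11643e-01
89,9.13496e-02,1.32203e-02,1.37255e-01,1.08445e-01
90,8.81843e-02,1.29313e-02,1.36921e-01,1.05395e-01
91,8.51609e-02,1.26515e-02,1.36590e-01,1.02484e-01
92,8.22716e-02,1.23805e-02,1.36260e-01,9.97060e-02
93,7.95090e-02,1.21179e-02,1.35934e-01,9.70526e-02
94,7.68664e-02,1.18633e-02,1.35609e-01,9.45174e-02
95,7.43374e-02,1.16165e-02,1.35287e-01,9.20940e-02
96,7.19160e-02,1.13769e-02,1.34966e-01,8.97766e-02
97,6.95965e-02,1.11444e-02,1.34648e-01,8.75595e-02
98,6.73739e-02,1.09187e-02,1.34332e-01,8.54377e-02
99,6.52431e-02,1.06994e-02,1.34019e-01,8.34060e-02
100,6.31994e-02,1.04863e-02,1.33707e-01,8.14601e-02
101,6.12385e-02,1.02791e-02,1.33397e-01,7.95955e-02
102,5.93563e-02,1.00776e-02,1.33090e-01,7.78082e-02
103,5.75490e-02,9.88161e-03,1.32784e-01,7.60943e-02
104,5.58128e-02,9.69086e-03,1.32480e-01,7.44503e-02
105,5.41444e-02,9.50514e-03,1.32179e-01,7.28728e-02
106,5.25405e-02,9.32427e-03,1.31879e-01,7.13584e-02
107,5.09981e-02,9.14805e-03,1.31581e-01,6.99043e-02
108,4.95143e-02,8.97631e-03,1.31286e-01,6.85076e-02
109,4.80863e-02,8.80888e-03,1.30992e-01,6.71655e-02
110,4.67115e-02,8.64560e-03,1.30700e-01,6.58755e-02
111,4.53877e-02,8.48630e-03,1.30410e-01,6.46353e-02
112,4.41123e-02,8.33086e-03,1.30121e-01,6.34425e-02
113,4.28834e-02,8.17911e-03,1.29835e-01,6.22949e-02
114,4.16987e-02,8.03095e-03,1.29550e-01,6.11906e-02
115,4.05564e-02,7.88622e-03,1.29267e-01,6.01276e-02
116,3.94545e-02,7.74483e-03,1.28986e-01,5.91041e-02
117,3.83914e-02,7.60664e-03,1.28707e-01,5.81182e-02
118,3.73654e-02,7.47155e-03,1.28429e-01,5.71685e-02
119,3.63748e-02,7.33946e-03,1.28153e-01,5.62533e-02
120,3.54182e-02,7.21027e-03,1.27879e-01,5.53711e-02
121,3.44941e-02,7.08388e-03,1.27607e-01,5.45206e-02
122,3.36013e-02,6.96019e-03,1.27336e-01,5.37003e-02
123,3.27383e-02,6.83913e-03,1.27067e-01,5.29091e-02
124,3.19041e-02,6.72061e-03,1.26799e-01,5.21456e-02
125,3.10973e-02,6.60455e-03,1.26533e-01,5.14088e-02
126,3.03169e-02,6.49088e-03,1.26269e-01,5.06976e-02
127,2.95619e-02,6.37951e-03,1.26006e-01,5.00109e-02
128,2.88312e-02,6.27039e-03,1.25745e-01,4.93476e-02
129,2.81239e-02,6.16345e-03,1.25486e-01,4.87070e-02
130,2.74390e-02,6.05862e-03,1.25228e-01,4.80880e-02
131,2.67757e-02,5.95585e-03,1.24971e-01,4.74898e-02
132,2.61331e-02,5.85507e-03,1.24716e-01,4.69116e-02
133,2.55105e-02,5.75623e-03,1.24463e-01,4.63527e-02
134,2.49071e-02,5.65927e-03,1.24211e-01,4.58121e-02
135,2.43222e-02,5.56415e-03,1.23961e-01,4.52893e-02
136,2.37550e-02,5.47082e-03,1.23712e-01,4.47836e-02
137,2.32050e-02,5.37922e-03,1.23464e-01,4.42943e-02
138,2.26714e-02,5.28932e-03,1.23218e-01,4.38208e-02
139,2.21537e-02,5.20108e-03,1.22973e-01,4.33625e-02
140,2.16513e-02,5.11444e-03,1.22730e-01,4.29188e-02
141,2.11636e-02,5.02937e-03,1.22488e-01,4.24892e-02
142,2.06902e-02,4.94583e-03,1.22248e-01,4.20731e-02
143,2.02304e-02,4.86379e-03,1.22008e-01,4.16701e-02
144,1.97839e-02,4.78321e-03,1.21771e-01,4.12797e-02
145,1.93501e-02,4.70405e-03,1.21534e-01,4.09014e-02
146,1.89287e-02,4.62628e-03,1.21299e-01,4.05349e-02
147,1.85191e-02,4.54988e-03,1.21065e-01,4.01795e-02
148,1.81210e-02,4.47480e-03,1.20833e-01,3.98351e-02
149,1.77339e-02,4.40103e-03,1.20602e-01,3.95012e-02
150,1.73576e-02,4.32852e-03,1.20372e-01,3.91774e-02
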