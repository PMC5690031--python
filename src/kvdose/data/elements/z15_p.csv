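# element P Z=15 A=30.974
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,3.24805e+02,1.50511e+00,1.90309e-01,3.17781e+02
6,1.90526e+02,1.23162e+00,1.89590e-01,1.87093e+02
7,1.21050e+02,1.01311e+00,1.88879e-01,1.19183e+02
8,8.15648e+01,8.41501e-01,1.88174e-01,8.04649e+01
9,5.74944e+01,7.07028e-01,1.87477e-01,5.68066e+01
10,4.20012e+01,6.00975e-01,1.86786e-01,4.15504e+01
11,3.15860e+01,5.16438e-01,1.86102e-01,3.12793e+01
12,2.43312e+01,4.48214e-01,1.85424e-01,2.41160e+01
13,1.91259e+01,3.92468e-01,1.84753e-01,1.89712e+01
14,1.52963e+01,3.46375e-01,1.84088e-01,1.51829e+01
15,1.24175e+01,3.07849e-01,1.83430e-01,1.23331e+01
16,1.02128e+01,2.75327e-01,1.82777e-01,1.01492e+01
17,8.49654e+00,2.47629e-01,1.82131e-01,8.44813e+00
18,7.14105e+00,2.23852e-01,1.81491e-01,7.10408e+00
19,6.05668e+00,2.03291e-01,1.80857e-01,6.02842e+00
20,5.17918e+00,1.85396e-01,1.80229e-01,5.15767e+00
21,4.46169e+00,1.69728e-01,1.79606e-01,4.44548e+00
22,3.86951e+00,1.55936e-01,1.78990e-01,3.85753e+00
23,3.37657e+00,1.43733e-01,1.78379e-01,3.36800e+00
24,2.96302e+00,1.32886e-01,1.77773e-01,2.95724e+00
25,2.61358e+00,1.23205e-01,1.77173e-01,2.61011e+00
26,2.31638e+00,1.14529e-01,1.76578e-01,2.31483e+00
27,2.06205e+00,1.06726e-01,1.75989e-01,2.06212e+00
28,1.84318e+00,9.96821e-02,1.75405e-01,1.84464e+00
29,1.65383e+00,9.33044e-02,1.74826e-01,1.65649e+00
30,1.48923e+00,8.75118e-02,1.74252e-01,1.49293e+00
31,1.34548e+00,8.22357e-02,1.73684e-01,1.35009e+00
32,1.21941e+00,7.74170e-02,1.73120e-01,1.22483e+00
33,1.10840e+00,7.30048e-02,1.72561e-01,1.11454e+00
34,1.01028e+00,6.89551e-02,1.72007e-01,1.01706e+00
35,9.23245e-01,6.52297e-02,1.71458e-01,9.30610e-01
36,8.45784e-01,6.17950e-02,1.70914e-01,8.53681e-01
37,7.76627e-01,5.86220e-02,1.70374e-01,7.85012e-01
38,7.14697e-01,5.56848e-02,1.69839e-01,7.23533e-01
39,6.59083e-01,5.29609e-02,1.69308e-01,6.68336e-01
40,6.09005e-01,5.04303e-02,1.68782e-01,6.18647e-01
41,5.63797e-01,4.80753e-02,1.68261e-01,5.73804e-01
42,5.22886e-01,4.58802e-02,1.67744e-01,5.33235e-01
43,4.85777e-01,4.38308e-02,1.67231e-01,4.96450e-01
44,4.52042e-01,4.19147e-02,1.66722e-01,4.63022e-01
45,4.21309e-01,4.01207e-02,1.66218e-01,4.32582e-01
46,3.93255e-01,3.84386e-02,1.65717e-01,4.04807e-01
47,3.67596e-01,3.68595e-02,1.65221e-01,3.79416e-01
48,3.44085e-01,3.53751e-02,1.64729e-01,3.56161e-01
49,3.22503e-01,3.39781e-02,1.64241e-01,3.34826e-01
50,3.02658e-01,3.26618e-02,1.63757e-01,3.15220e-01
51,2.84381e-01,3.14201e-02,1.63277e-01,2.97173e-01
52,2.67521e-01,3.02477e-02,1.62801e-01,2.80535e-01
53,2.51944e-01,2.91393e-02,1.62328e-01,2.65175e-01
54,2.37532e-01,2.80906e-02,1.61859e-01,2.50973e-01
55,2.24180e-01,2.70974e-02,1.61394e-01,2.37824e-01
56,2.11791e-01,2.61558e-02,1.60933e-01,2.25635e-01
57,2.00283e-01,2.52623e-02,1.60475e-01,2.14320e-01
58,1.89578e-01,2.44137e-02,1.60021e-01,2.03804e-01
59,1.79609e-01,2.36072e-02,1.59571e-01,1.94020e-01
60,1.70313e-01,2.28400e-02,1.59124e-01,1.84905e-01
61,1.61637e-01,2.21096e-02,1.58680e-01,1.76405e-01
62,1.53529e-01,2.14137e-02,1.58240e-01,1.68470e-01
63,1.45944e-01,2.07502e-02,1.57803e-01,1.61054e-01
64,1.38841e-01,2.01171e-02,1.57370e-01,1.54117e-01
65,1.32182e-01,1.95126e-02,1.56940e-01,1.47622e-01
66,1.25935e-01,1.89350e-02,1.56513e-01,1.41535e-01
67,1.20067e-01,1.83827e-02,1.56089e-01,1.35824e-01
68,1.14552e-01,1.78544e-02,1.55669e-01,1.30463e-01
69,1.09362e-01,1.73485e-02,1.55252e-01,1.25425e-01
70,1.04475e-01,1.68639e-02,1.54838e-01,1.20687e-01
71,9.98696e-02,1.63995e-02,1.54427e-01,1.16227e-01
72,9.55252e-02,1.59539e-02,1.54019e-01,1.12027e-01
73,9.14241e-02,1.55264e-02,1.53614e-01,1.08068e-01
74,8.75497e-02,1.51158e-02,1.53212e-01,1.04333e-01
75,8.38868e-02,1.47213e-02,1.52813e-01,1.00808e-01
76,8.04212e-02,1.43421e-02,1.52416e-01,9.74774e-02
77,7.71400e-02,1.39773e-02,1.52023e-01,9.43295e-02
78,7.40313e-02,1.36263e-02,1.51633e-01,9.13521e-02
79,7.10839e-02,1.32883e-02,1.51245e-01,8.85341e-02
80,6.82877e-02,1.29626e-02,1.50860e-01,8.58654e-02
81,6.56331e-02,1.26486e-02,1.50478e-01,8.33366e-02
82,6.31116e-02,1.23459e-02,1.50099e-01,8.09389e-02
83,6.07148e-02,1.20537e-02,1.49722e-01,7.86643e-02
84,5.84353e-02,1.17717e-02,1.49348e-01,7.65053e-02
85,5.62661e-02,1.14993e-02,1.48977e-01,7.44550e-02
86,5.42006e-02,1.12360e-02,1.48608e-01,7.25067e-02
87,5.22329e-02,1.09815e-02,1.48242e-01,7.06546e-02
88,5.03572e-02,1.07353e-02,1.47878e-01,6.88931e-02
89,4.85683e-02,1.04970e-02,1.47517e-01,6.72168e-02
90,4.68613e-02,1.02663e-02,1.47159e-01,6.56209e-02
91,4.52317e-02,1.00429e-02,1.46803e-01,6.41009e-02
92,4.36751e-02,9.82630e-03,1.46449e-01,6.26526e-02
93,4.21875e-02,9.61635e-03,1.46098e-01,6.12719e-02
94,4.07652e-02,9.41270e-03,1.45749e-01,5.99551e-02
95,3.94048e-02,9.21509e-03,1.45402e-01,5.86988e-02
96,3.81029e-02,9.02325e-03,1.45058e-01,5.74997e-02
97,3.68564e-02,8.83693e-03,1.44716e-01,5.63548e-02
98,3.56625e-02,8.65591e-03,1.44377e-01,5.52612e-02
99,3.45185e-02,8.47996e-03,1.44039e-01,5.42162e-02
100,3.34217e-02,8.30886e-03,1.43704e-01,5.32173e-02
101,3.23699e-02,8.14243e-03,1.43372e-01,5.22621e-02
102,3.13608e-02,7.98047e-03,1.43041e-01,5.13484e-02
103,3.03923e-02,7.82280e-03,1.42713e-01,5.04741e-02
104,2.94623e-02,7.66925e-03,1.42386e-01,4.96373e-02
105,2.85690e-02,7.51966e-03,1.42062e-01,4.88360e-02
106,2.77106e-02,7.37388e-03,1.41740e-01,4.80685e-02
107,2.68855e-02,7.23176e-03,1.41420e-01,4.73332e-02
108,2.60920e-02,7.09316e-03,1.41102e-01,4.66285e-02
109,2.53288e-02,6.95795e-03,1.40786e-01,4.59530e-02
110,2.45943e-02,6.82602e-03,1.40472e-01,4.53052e-02
111,2.38873e-02,6.69722e-03,1.40161e-01,4.46839e-02
112,2.32065e-02,6.57147e-03,1.39851e-01,4.40877e-02
113,2.25508e-02,6.44864e-03,1.39543e-01,4.35156e-02
114,2.19189e-02,6.32863e-03,1.39237e-01,4.29664e-02
115,2.13099e-02,6.21136e-03,1.38933e-01,4.24392e-02
116,2.07226e-02,6.09672e-03,1.38631e-01,4.19327e-02
117,2.01563e-02,5.98462e-03,1.38331e-01,4.14463e-02
118,1.96099e-02,5.87499e-03,1.38032e-01,4.09788e-02
119,1.90826e-02,5.76774e-03,1.37736e-01,4.05296e-02
120,1.85736e-02,5.66280e-03,1.37441e-01,4.00978e-02
121,1.80821e-02,5.56009e-03,1.37148e-01,3.96826e-02
122,1.76074e-02,5.45955e-03,1.36857e-01,3.92833e-02
123,1.71488e-02,5.36110e-03,1.36568e-01,3.88992e-02
124,1.67056e-02,5.26469e-03,1.36280e-01,3.85297e-02
125,1.62771e-02,5.17025e-03,1.35995e-01,3.81742e-02
126,1.58628e-02,5.07773e-03,1.35711e-01,3.78320e-02
127,1.54621e-02,4.98707e-03,1.35428e-01,3.75026e-02
128,1.50745e-02,4.89822e-03,1.35148e-01,3.71855e-02
129,1.46994e-02,4.81113e-03,1.34869e-01,3.68802e-02
130,1.43363e-02,4.72575e-03,1.34591e-01,3.65861e-02
131,1.39848e-02,4.64203e-03,1.34316e-01,3.63028e-02
132,1.36445e-02,4.55993e-03,1.34042e-01,3.60298e-02
133,1.33148e-02,4.47941e-03,1.33769e-01,3.57669e-02
134,1.29953e-02,4.40043e-03,1.33499e-01,3.55134e-02
135,1.26858e-02,4.32294e-03,1.33229e-01,3.52692e-02
136,1.23858e-02,4.24691e-03,1.32962e-01,3.50337e-02
137,1.20949e-02,4.17231e-03,1.32696e-01,3.48067e-02
138,1.18128e-02,4.09909e-03,1.32431e-01,3.45878e-02
139,1.15392e-02,4.02724e-03,1.32168e-01,3.43767e-02
140,1.12738e-02,3.95670e-03,1.31907e-01,3.41731e-02
141,1.10163e-02,3.88746e-03,1.31647e-01,3.39768e-02
142,1.07664e-02,3.81948e-03,1.31388e-01,3.37873e-02
143,1.05237e-02,3.75274e-03,1.31131e-01,3.36046e-02
144,1.02881e-02,3.68720e-03,1.30876e-01,3.34282e-02
145,1.00594e-02,3.62285e-03,1.30622e-01,3.32580e-02
146,9.83714e-03,3.55965e-03,1.30369e-01,3.30938e-02
147,9.62126e-03,3.49758e-03,1.30118e-01,3.29352e-02
148,9.41148e-03,3.43662e-03,1.29868e-01,3.27822e-02
149,9.20761e-03,3.37674e-03,1.29619e-01,3.26345e-02
150,9.00943e-03,3.31792e-03,1.29372e-01,3.24919e-02
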