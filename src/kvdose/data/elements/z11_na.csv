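# element Na Z=11 A=22.99
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,1.21432e+02,9.77452e-01,1.88026e-01,1.20955e+02
6,7.02203e+01,7.84690e-01,1.87316e-01,6.99918e+01
7,4.40790e+01,6.36542e-01,1.86613e-01,4.39574e+01
8,2.93918e+01,5.23529e-01,1.85917e-01,2.93222e+01
9,2.05278e+01,4.36781e-01,1.85228e-01,2.04860e+01
10,1.48728e+01,3.69337e-01,1.84546e-01,1.48470e+01
11,1.11016e+01,3.16103e-01,1.83870e-01,1.10855e+01
12,8.49365e+00,2.73440e-01,1.83200e-01,8.48379e+00
13,6.63483e+00,2.38758e-01,1.82537e-01,6.62917e+00
14,5.27561e+00,2.10198e-01,1.81880e-01,5.27289e+00
15,4.25967e+00,1.86406e-01,1.81230e-01,4.25907e+00
16,3.48571e+00,1.66381e-01,1.80585e-01,3.48671e+00
17,2.88619e+00,1.49372e-01,1.79947e-01,2.88842e+00
18,2.41491e+00,1.34806e-01,1.79314e-01,2.41813e+00
19,2.03955e+00,1.22239e-01,1.78688e-01,2.04358e+00
20,1.73706e+00,1.11325e-01,1.78067e-01,1.74177e+00
21,1.49071e+00,1.01788e-01,1.77452e-01,1.49601e+00
22,1.28816e+00,9.34081e-02,1.76843e-01,1.29396e+00
23,1.12015e+00,8.60070e-02,1.76239e-01,1.12641e+00
24,9.79685e-01,7.94396e-02,1.75641e-01,9.86362e-01
25,8.61391e-01,7.35863e-02,1.75048e-01,8.68449e-01
26,7.61095e-01,6.83484e-02,1.74460e-01,7.68507e-01
27,6.75529e-01,6.36433e-02,1.73878e-01,6.83273e-01
28,6.02110e-01,5.94018e-02,1.73301e-01,6.10167e-01
29,5.38774e-01,5.55657e-02,1.72729e-01,5.47130e-01
30,4.83865e-01,5.20852e-02,1.72162e-01,4.92506e-01
31,4.36039e-01,4.89183e-02,1.71600e-01,4.44955e-01
32,3.94201e-01,4.60285e-02,1.71044e-01,4.03382e-01
33,3.57451e-01,4.33849e-02,1.70491e-01,3.66889e-01
34,3.25047e-01,4.09605e-02,1.69944e-01,3.34733e-01
35,2.96371e-01,3.87319e-02,1.69402e-01,3.06299e-01
36,2.70907e-01,3.66787e-02,1.68864e-01,2.81071e-01
37,2.48222e-01,3.47831e-02,1.68331e-01,2.58617e-01
38,2.27952e-01,3.30296e-02,1.67802e-01,2.38573e-01
39,2.09787e-01,3.14044e-02,1.67278e-01,2.20628e-01
40,1.93463e-01,2.98954e-02,1.66758e-01,2.04520e-01
41,1.78755e-01,2.84918e-02,1.66243e-01,1.90025e-01
42,1.65472e-01,2.71841e-02,1.65732e-01,1.76949e-01
43,1.53445e-01,2.59639e-02,1.65225e-01,1.65127e-01
44,1.42532e-01,2.48236e-02,1.64722e-01,1.54415e-01
45,1.32608e-01,2.37563e-02,1.64224e-01,1.44689e-01
46,1.23565e-01,2.27561e-02,1.63730e-01,1.35840e-01
47,1.15309e-01,2.18175e-02,1.63240e-01,1.27774e-01
48,1.07756e-01,2.09356e-02,1.62753e-01,1.20409e-01
49,1.00834e-01,2.01059e-02,1.62271e-01,1.13672e-01
50,9.44796e-02,1.93244e-02,1.61793e-01,1.07500e-01
51,8.86365e-02,1.85875e-02,1.61319e-01,1.01837e-01
52,8.32547e-02,1.78919e-02,1.60848e-01,9.66316e-02
53,7.82902e-02,1.72346e-02,1.60381e-01,9.18413e-02
54,7.37039e-02,1.66128e-02,1.59918e-01,8.74266e-02
55,6.94608e-02,1.60241e-02,1.59459e-01,8.33527e-02
56,6.55298e-02,1.54662e-02,1.59003e-01,7.95885e-02
57,6.18831e-02,1.49369e-02,1.58551e-01,7.61062e-02
58,5.84958e-02,1.44344e-02,1.58102e-01,7.28810e-02
59,5.53456e-02,1.39569e-02,1.57657e-01,6.98907e-02
60,5.24123e-02,1.35028e-02,1.57215e-01,6.71150e-02
61,4.96777e-02,1.30705e-02,1.56777e-01,6.45360e-02
62,4.71257e-02,1.26587e-02,1.56342e-01,6.21373e-02
63,4.47414e-02,1.22662e-02,1.55911e-01,5.99043e-02
64,4.25114e-02,1.18917e-02,1.55482e-01,5.78236e-02
65,4.04236e-02,1.15341e-02,1.55058e-01,5.58831e-02
66,3.84670e-02,1.11924e-02,1.54636e-01,5.40719e-02
67,3.66316e-02,1.08658e-02,1.54217e-01,5.23799e-02
68,3.49083e-02,1.05532e-02,1.53802e-01,5.07982e-02
69,3.32887e-02,1.02539e-02,1.53390e-01,4.93183e-02
70,3.17654e-02,9.96720e-03,1.52981e-01,4.79329e-02
71,3.03313e-02,9.69230e-03,1.52574e-01,4.66349e-02
72,2.89801e-02,9.42856e-03,1.52171e-01,4.54180e-02
73,2.77060e-02,9.17537e-03,1.51771e-01,4.42765e-02
74,2.65036e-02,8.93216e-03,1.51374e-01,4.32051e-02
75,2.53680e-02,8.69838e-03,1.50980e-01,4.21988e-02
76,2.42948e-02,8.47352e-03,1.50588e-01,4.12532e-02
77,2.32797e-02,8.25713e-03,1.50200e-01,4.03641e-02
78,2.23190e-02,8.04874e-03,1.49814e-01,3.95278e-02
79,2.14090e-02,7.84795e-03,1.49431e-01,3.87407e-02
80,2.05466e-02,7.65437e-03,1.49051e-01,3.79997e-02
81,1.97287e-02,7.46763e-03,1.48674e-01,3.73016e-02
82,1.89525e-02,7.28739e-03,1.48299e-01,3.66437e-02
83,1.82155e-02,7.11332e-03,1.47927e-01,3.60236e-02
84,1.75151e-02,6.94512e-03,1.47557e-01,3.54387e-02
85,1.68493e-02,6.78250e-03,1.47190e-01,3.48869e-02
86,1.62159e-02,6.62520e-03,1.46826e-01,3.43661e-02
87,1.56131e-02,6.47296e-03,1.46464e-01,3.38745e-02
88,1.50389e-02,6.32554e-03,1.46105e-01,3.34103e-02
89,1.44919e-02,6.18272e-03,1.45748e-01,3.29718e-02
90,1.39703e-02,6.04428e-03,1.45394e-01,3.25575e-02
91,1.34728e-02,5.91003e-03,1.45042e-01,3.21660e-02
92,1.29980e-02,5.77978e-03,1.44693e-01,3.17959e-02
93,1.25447e-02,5.65335e-03,1.44345e-01,3.14460e-02
94,1.21116e-02,5.53058e-03,1.44001e-01,3.11151e-02
95,1.16977e-02,5.41130e-03,1.43658e-01,3.08022e-02
96,1.13020e-02,5.29536e-03,1.43318e-01,3.05063e-02
97,1.09234e-02,5.18263e-03,1.42981e-01,3.02263e-02
98,1.05610e-02,5.07298e-03,1.42645e-01,2.99614e-02
99,1.02141e-02,4.96626e-03,1.42312e-01,2.97108e-02
100,9.88181e-03,4.86238e-03,1.41981e-01,2.94737e-02
101,9.56337e-03,4.76121e-03,1.41652e-01,2.92493e-02
102,9.25809e-03,4.66265e-03,1.41325e-01,2.90370e-02
103,8.96530e-03,4.56660e-03,1.41001e-01,2.88361e-02
104,8.68439e-03,4.47295e-03,1.40678e-01,2.86460e-02
105,8.41477e-03,4.38163e-03,1.40358e-01,2.84662e-02
106,8.15588e-03,4.29255e-03,1.40040e-01,2.82961e-02
107,7.90721e-03,4.20562e-03,1.39724e-01,2.81351e-02
108,7.66827e-03,4.12077e-03,1.39410e-01,2.79829e-02
109,7.43858e-03,4.03793e-03,1.39098e-01,2.78389e-02
110,7.21772e-03,3.95702e-03,1.38788e-01,2.77028e-02
111,7.00527e-03,3.87798e-03,1.38480e-01,2.75741e-02
112,6.80084e-03,3.80075e-03,1.38173e-01,2.74525e-02
113,6.60407e-03,3.72527e-03,1.37869e-01,2.73377e-02
114,6.41459e-03,3.65148e-03,1.37567e-01,2.72291e-02
115,6.23209e-03,3.57933e-03,1.37267e-01,2.71267e-02
116,6.05625e-03,3.50876e-03,1.36968e-01,2.70300e-02
117,5.88678e-03,3.43974e-03,1.36671e-01,2.69388e-02
118,5.72339e-03,3.37221e-03,1.36377e-01,2.68528e-02
119,5.56581e-03,3.30613e-03,1.36084e-01,2.67718e-02
120,5.41381e-03,3.24145e-03,1.35793e-01,2.66954e-02
121,5.26712e-03,3.17814e-03,1.35503e-01,2.66236e-02
122,5.12554e-03,3.11616e-03,1.35216e-01,2.65560e-02
123,4.98884e-03,3.05547e-03,1.34930e-01,2.64925e-02
124,4.85681e-03,2.99604e-03,1.34646e-01,2.64329e-02
125,4.72927e-03,2.93783e-03,1.34364e-01,2.63769e-02
126,4.60602e-03,2.88081e-03,1.34083e-01,2.63245e-02
127,4.48690e-03,2.82495e-03,1.33804e-01,2.62754e-02
128,4.37173e-03,2.77022e-03,1.33527e-01,2.62295e-02
129,4.26035e-03,2.71659e-03,1.33251e-01,2.61866e-02
130,4.15261e-03,2.66403e-03,1.32977e-01,2.61466e-02
131,4.04836e-03,2.61253e-03,1.32705e-01,2.61094e-02
132,3.94748e-03,2.56204e-03,1.32434e-01,2.60748e-02
133,3.84982e-03,2.51256e-03,1.32165e-01,2.60428e-02
134,3.75526e-03,2.46405e-03,1.31897e-01,2.60131e-02
135,3.66367e-03,2.41650e-03,1.31632e-01,2.59857e-02
136,3.57496e-03,2.36987e-03,1.31367e-01,2.59605e-02
137,3.48900e-03,2.32416e-03,1.31104e-01,2.59373e-02
138,3.40569e-03,2.27934e-03,1.30843e-01,2.59162e-02
139,3.32494e-03,2.23539e-03,1.30583e-01,2.58969e-02
140,3.24664e-03,2.19229e-03,1.30325e-01,2.58794e-02
141,3.17070e-03,2.15002e-03,1.30068e-01,2.58637e-02
142,3.09705e-03,2.10857e-03,1.29813e-01,2.58496e-02
143,3.02559e-03,2.06792e-03,1.29559e-01,2.58370e-02
144,2.95625e-03,2.02805e-03,1.29306e-01,2.58260e-02
145,2.88894e-03,1.98895e-03,1.29055e-01,2.58164e-02
146,2.82360e-03,1.95060e-03,1.28805e-01,2.58081e-02
147,2.76016e-03,1.91298e-03,1.28557e-01,2.58011e-02
148,2.69855e-03,1.87609e-03,1.28310e-01,2.57954e-02
149,2.63870e-03,1.83990e-03,1.28065e-01,2.57909e-02
150,2.58055e-03,1.80440e-03,1.27821e-01,2.57874e-02
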