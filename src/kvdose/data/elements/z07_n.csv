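# element N Z=7 A=14.007
energy_kev,pe_cm2_g,coh_cm2_g,incoh_cm2_g,en_abs_cm2_g
5,3.07741e+01,5.43087e-01,1.96389e-01,3.07655e+01
6,1.74292e+01,4.25185e-01,1.95648e-01,1.74265e+01
7,1.07499e+01,3.39082e-01,1.94914e-01,1.07499e+01
8,7.05959e+00,2.75656e-01,1.94187e-01,7.06102e+00
9,4.86471e+00,2.28081e-01,1.93467e-01,4.86707e+00
10,3.48246e+00,1.91650e-01,1.92754e-01,3.48548e+00
11,2.57130e+00,1.63192e-01,1.92048e-01,2.57485e+00
12,1.94782e+00,1.40558e-01,1.91348e-01,1.95181e+00
13,1.50770e+00,1.22267e-01,1.90656e-01,1.51210e+00
14,1.18874e+00,1.07280e-01,1.89970e-01,1.19350e+00
15,9.52288e-01,9.48513e-02,1.89290e-01,9.57401e-01
16,7.73543e-01,8.44326e-02,1.88617e-01,7.78987e-01
17,6.36082e-01,7.56158e-02,1.87950e-01,6.41846e-01
18,5.28756e-01,6.80912e-02,1.87290e-01,5.34830e-01
19,4.43821e-01,6.16203e-02,1.86636e-01,4.50199e-01
20,3.75792e-01,5.60169e-02,1.85987e-01,3.82464e-01
21,3.20706e-01,5.11341e-02,1.85345e-01,3.27669e-01
22,2.75661e-01,4.68545e-02,1.84708e-01,2.82907e-01
23,2.38495e-01,4.30837e-02,1.84078e-01,2.46020e-01
24,2.07578e-01,3.97450e-02,1.83453e-01,2.15377e-01
25,1.81665e-01,3.67753e-02,1.82834e-01,1.89733e-01
26,1.59796e-01,3.41227e-02,1.82220e-01,1.68129e-01
27,1.41221e-01,3.17440e-02,1.81612e-01,1.49815e-01
28,1.25351e-01,2.96032e-02,1.81009e-01,1.34202e-01
29,1.11717e-01,2.76697e-02,1.80412e-01,1.20820e-01
30,9.99439e-02,2.59179e-02,1.79820e-01,1.09296e-01
31,8.97289e-02,2.43259e-02,1.79233e-01,9.93259e-02
32,8.08259e-02,2.28749e-02,1.78651e-01,9.06644e-02
33,7.30339e-02,2.15490e-02,1.78075e-01,8.31102e-02
34,6.61872e-02,2.03342e-02,1.77503e-01,7.64978e-02
35,6.01487e-02,1.92186e-02,1.76936e-01,7.06902e-02
36,5.48042e-02,1.81918e-02,1.76375e-01,6.55734e-02
37,5.00584e-02,1.72446e-02,1.75818e-01,6.10519e-02
38,4.58308e-02,1.63690e-02,1.75265e-01,5.70454e-02
39,4.20537e-02,1.55582e-02,1.74718e-01,5.34863e-02
40,3.86695e-02,1.48059e-02,1.74175e-01,5.03170e-02
41,3.56293e-02,1.41066e-02,1.73637e-01,4.74885e-02
42,3.28910e-02,1.34555e-02,1.73103e-01,4.49591e-02
43,3.04186e-02,1.28484e-02,1.72574e-01,4.26927e-02
44,2.81812e-02,1.22813e-02,1.72049e-01,4.06584e-02
45,2.61519e-02,1.17509e-02,1.71528e-01,3.88293e-02
46,2.43075e-02,1.12542e-02,1.71012e-01,3.71824e-02
47,2.26276e-02,1.07882e-02,1.70500e-01,3.56973e-02
48,2.10947e-02,1.03507e-02,1.69992e-01,3.43565e-02
49,1.96933e-02,9.93923e-03,1.69489e-01,3.31445e-02
50,1.84098e-02,9.55188e-03,1.68989e-01,3.20479e-02
51,1.72322e-02,9.18679e-03,1.68494e-01,3.10547e-02
52,1.61501e-02,8.84229e-03,1.68002e-01,3.01544e-02
53,1.51541e-02,8.51687e-03,1.67515e-01,2.93378e-02
54,1.42359e-02,8.20914e-03,1.67031e-01,2.85967e-02
55,1.33883e-02,7.91784e-03,1.66551e-01,2.79237e-02
56,1.26047e-02,7.64182e-03,1.66075e-01,2.73123e-02
57,1.18792e-02,7.38002e-03,1.65603e-01,2.67569e-02
58,1.12067e-02,7.13146e-03,1.65134e-01,2.62522e-02
59,1.05825e-02,6.89526e-03,1.64669e-01,2.57935e-02
60,1.00024e-02,6.67060e-03,1.64208e-01,2.53768e-02
61,9.46269e-03,6.45671e-03,1.63750e-01,2.49983e-02
62,8.95993e-03,6.25290e-03,1.63296e-01,2.46546e-02
63,8.49108e-03,6.05853e-03,1.62845e-01,2.43428e-02
64,8.05337e-03,5.87300e-03,1.62398e-01,2.40601e-02
65,7.64432e-03,5.69575e-03,1.61954e-01,2.38041e-02
66,7.26165e-03,5.52628e-03,1.61514e-01,2.35725e-02
67,6.90331e-03,5.36412e-03,1.61077e-01,2.33632e-02
68,6.56744e-03,5.20882e-03,1.60643e-01,2.31745e-02
69,6.25232e-03,5.05997e-03,1.60212e-01,2.30047e-02
70,5.95641e-03,4.91721e-03,1.59785e-01,2.28522e-02
71,5.67830e-03,4.78016e-03,1.59361e-01,2.27157e-02
72,5.41669e-03,4.64851e-03,1.58940e-01,2.25939e-02
73,5.17040e-03,4.52195e-03,1.58522e-01,2.24857e-02
74,4.93834e-03,4.40020e-03,1.58107e-01,2.23899e-02
75,4.71952e-03,4.28299e-03,1.57695e-01,2.23057e-02
76,4.51302e-03,4.17007e-03,1.57286e-01,2.22322e-02
77,4.31801e-03,4.06121e-03,1.56880e-01,2.21684e-02
78,4.13372e-03,3.95619e-03,1.56478e-01,2.21138e-02
79,3.95942e-03,3.85483e-03,1.56078e-01,2.20675e-02
80,3.79447e-03,3.75692e-03,1.55680e-01,2.20290e-02
81,3.63826e-03,3.66229e-03,1.55286e-01,2.19977e-02
82,3.49023e-03,3.57077e-03,1.54895e-01,2.19730e-02
83,3.34986e-03,3.48223e-03,1.54506e-01,2.19545e-02
84,3.21667e-03,3.39650e-03,1.54120e-01,2.19416e-02
85,3.09021e-03,3.31345e-03,1.53737e-01,2.19341e-02
86,2.97008e-03,3.23297e-03,1.53356e-01,2.19314e-02
87,2.85589e-03,3.15492e-03,1.52979e-01,2.19332e-02
88,2.74729e-03,3.07920e-03,1.52603e-01,2.19392e-02
89,2.64394e-03,3.00571e-03,1.52231e-01,2.19491e-02
90,2.54553e-03,2.93435e-03,1.51861e-01,2.19626e-02
91,2.45179e-03,2.86503e-03,1.51493e-01,2.19794e-02
92,2.36244e-03,2.79765e-03,1.51128e-01,2.19993e-02
93,2.27723e-03,2.73215e-03,1.50766e-01,2.20220e-02
94,2.19593e-03,2.66844e-03,1.50406e-01,2.20473e-02
95,2.11833e-03,2.60645e-03,1.50048e-01,2.20751e-02
96,2.04422e-03,2.54612e-03,1.49693e-01,2.21051e-02
97,1.97341e-03,2.48738e-03,1.49340e-01,2.21372e-02
98,1.90572e-03,2.43017e-03,1.48990e-01,2.21712e-02
99,1.84098e-03,2.37443e-03,1.48642e-01,2.22070e-02
100,1.77904e-03,2.32012e-03,1.48296e-01,2.22443e-02
101,1.71976e-03,2.26718e-03,1.47952e-01,2.22832e-02
102,1.66299e-03,2.21557e-03,1.47611e-01,2.23235e-02
103,1.60861e-03,2.16523e-03,1.47272e-01,2.23650e-02
104,1.55649e-03,2.11613e-03,1.46936e-01,2.24077e-02
105,1.50652e-03,2.06822e-03,1.46601e-01,2.24514e-02
106,1.45859e-03,2.02148e-03,1.46269e-01,2.24961e-02
107,1.41260e-03,1.97585e-03,1.45938e-01,2.25417e-02
108,1.36846e-03,1.93132e-03,1.45610e-01,2.25881e-02
109,1.32607e-03,1.88783e-03,1.45284e-01,2.26352e-02
110,1.28536e-03,1.84537e-03,1.44961e-01,2.26829e-02
111,1.24624e-03,1.80390e-03,1.44639e-01,2.27312e-02
112,1.20863e-03,1.76340e-03,1.44319e-01,2.27801e-02
113,1.17247e-03,1.72383e-03,1.44001e-01,2.28294e-02
114,1.13769e-03,1.68517e-03,1.43686e-01,2.28792e-02
115,1.10422e-03,1.64740e-03,1.43372e-01,2.29293e-02
116,1.07200e-03,1.61049e-03,1.43060e-01,2.29797e-02
117,1.04099e-03,1.57442e-03,1.42750e-01,2.30304e-02
118,1.01111e-03,1.53917e-03,1.42442e-01,2.30813e-02
119,9.82325e-04,1.50472e-03,1.42136e-01,2.31324e-02
120,9.54585e-04,1.47104e-03,1.41832e-01,2.31837e-02
121,9.27842e-04,1.43812e-03,1.41530e-01,2.32351e-02
122,9.02053e-04,1.40594e-03,1.41230e-01,2.32866e-02
123,8.77177e-04,1.37448e-03,1.40931e-01,2.33381e-02
124,8.53174e-04,1.34372e-03,1.40635e-01,2.33897e-02
125,8.30008e-04,1.31364e-03,1.40340e-01,2.34413e-02
126,8.07643e-04,1.28424e-03,1.40047e-01,2.34928e-02
127,7.86045e-04,1.25549e-03,1.39755e-01,2.35444e-02
128,7.65183e-04,1.22738e-03,1.39466e-01,2.35958e-02
129,7.45027e-04,1.19989e-03,1.39178e-01,2.36472e-02
130,7.25546e-04,1.17301e-03,1.38892e-01,2.36985e-02
131,7.06714e-04,1.14673e-03,1.38607e-01,2.37496e-02
132,6.88505e-04,1.12103e-03,1.38325e-01,2.38007e-02
133,6.70893e-04,1.09590e-03,1.38043e-01,2.38515e-02
134,6.53855e-04,1.07133e-03,1.37764e-01,2.39022e-02
135,6.37368e-04,1.04730e-03,1.37486e-01,2.39528e-02
136,6.21410e-04,1.02380e-03,1.37210e-01,2.40031e-02
137,6.05962e-04,1.00083e-03,1.36935e-01,2.40533e-02
138,5.91002e-04,9.78358e-04,1.36663e-01,2.41032e-02
139,5.76513e-04,9.56389e-04,1.36391e-01,2.41529e-02
140,5.62476e-04,9.34906e-04,1.36121e-01,2.42024e-02
141,5.48875e-04,9.13899e-04,1.35853e-01,2.42517e-02
142,5.35692e-04,8.93359e-04,1.35586e-01,2.43007e-02
143,5.22913e-04,8.73275e-04,1.35321e-01,2.43494e-02
144,5.10522e-04,8.53637e-04,1.35057e-01,2.43979e-02
145,4.98505e-04,8.34435e-04,1.34795e-01,2.44461e-02
146,4.86849e-04,8.15661e-04,1.34534e-01,2.44940e-02
147,4.75539e-04,7.97304e-04,1.34275e-01,2.45417e-02
148,4.64564e-04,7.79357e-04,1.34017e-01,2.45891e-02
149,4.53912e-04,7.61809e-04,1.33761e-01,2.46362e-02
150,4.43571e-04,7.44653e-04,1.33506e-01,2.46830e-02
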