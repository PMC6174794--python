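# 120 kVp tungsten-anode spectrum, 1 keV bins, 7 mm Al-equivalent total filtration.
# Computed from the package's filtered-Kramers model with K characteristic lines
# (synthetic tabulation; regenerate with ctdosim.source.tungsten_spectrum).
# energy_keV  relative_fluence
10.0	8.37526943e-23
11.0	1.56404032e-17
12.0	6.76609339e-14
13.0	2.61997154e-11
14.0	2.03762172e-09
15.0	5.26709633e-08
16.0	6.65144918e-07
17.0	4.69189486e-06
18.0	2.15998058e-05
19.0	7.23215391e-05
20.0	1.90211575e-04
21.0	4.20640970e-04
22.0	8.02075502e-04
23.0	1.36106926e-03
24.0	2.10514932e-03
25.0	3.02246583e-03
26.0	4.08561425e-03
27.0	5.25741111e-03
28.0	6.49672144e-03
29.0	7.76320479e-03
30.0	9.02056530e-03
31.0	1.02468140e-02
32.0	1.14097872e-02
33.0	1.24916490e-02
34.0	1.34804291e-02
35.0	1.43691683e-02
36.0	1.51549880e-02
37.0	1.58381936e-02
38.0	1.64214712e-02
39.0	1.69092017e-02
40.0	1.73068997e-02
41.0	1.76165306e-02
42.0	1.78492827e-02
43.0	1.80117756e-02
44.0	1.81105203e-02
45.0	1.81517903e-02
46.0	1.81415376e-02
47.0	1.80853407e-02
48.0	1.79883774e-02
49.0	1.78554168e-02
50.0	1.76908229e-02
51.0	1.74942845e-02
52.0	1.72741414e-02
53.0	1.70336049e-02
54.0	1.67755632e-02
55.0	1.65026060e-02
56.0	1.62170497e-02
57.0	1.59209617e-02
58.0	4.30493383e-02
59.0	6.34326930e-02
60.0	1.49869163e-02
61.0	1.46630998e-02
62.0	1.43363133e-02
63.0	1.40075422e-02
64.0	1.36776537e-02
65.0	1.33474091e-02
66.0	1.30174751e-02
67.0	2.32766696e-02
68.0	1.23607942e-02
69.0	1.58852627e-02
70.0	1.17114189e-02
71.0	1.13903931e-02
72.0	1.10721989e-02
73.0	1.07570758e-02
74.0	1.04452261e-02
75.0	1.01368194e-02
76.0	9.83199585e-03
77.0	9.53087022e-03
78.0	9.23353430e-03
79.0	8.94005978e-03
80.0	8.65050062e-03
81.0	8.36467664e-03
82.0	8.08285261e-03
83.0	7.80503956e-03
84.0	7.53123803e-03
85.0	7.26143941e-03
86.0	6.99562710e-03
87.0	6.73377754e-03
88.0	6.47586119e-03
89.0	6.22184332e-03
90.0	5.97168476e-03
91.0	5.72534256e-03
92.0	5.48277054e-03
93.0	5.24391986e-03
94.0	5.00873944e-03
95.0	4.77717638e-03
96.0	4.54917631e-03
97.0	4.32468373e-03
98.0	4.10364225e-03
99.0	3.88599489e-03
100.0	3.67168426e-03
101.0	3.46068551e-03
102.0	3.25290364e-03
103.0	3.04828139e-03
104.0	2.84676169e-03
105.0	2.64828785e-03
106.0	2.45280359e-03
107.0	2.26025315e-03
108.0	2.07058139e-03
109.0	1.88373381e-03
110.0	1.69965663e-03
111.0	1.51829680e-03
112.0	1.33960208e-03
113.0	1.16352107e-03
114.0	9.90003185e-04
115.0	8.18998717e-04
116.0	6.50458842e-04
117.0	4.84335622e-04
118.0	3.20582017e-04
119.0	1.59151889e-04
120.0	0.00000000e+00
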