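# Synthetic parametric 120 kVp tungsten spectrum: Kramers bremsstrahlung
# filtered by 6.0 mm equivalent aluminum, with K lines added.
# Weights are relative fluence per bin and sum to 1.
energy_keV,weight
10.0,4.128803e-19
12.0,1.238633e-11
14.0,6.395852e-08
16.0,9.320503e-06
18.0,1.522383e-04
20.0,9.145755e-04
22.0,2.967142e-03
24.0,6.557283e-03
26.0,1.135636e-02
28.0,1.677578e-02
30.0,2.149530e-02
32.0,2.578739e-02
34.0,2.962146e-02
36.0,3.213457e-02
38.0,3.406045e-02
40.0,3.532532e-02
42.0,3.582461e-02
44.0,3.602924e-02
46.0,3.566942e-02
48.0,3.512377e-02
50.0,3.431403e-02
52.0,3.329964e-02
54.0,3.228063e-02
56.0,3.100721e-02
58.0,7.489742e-02
60.0,5.692962e-02
62.0,2.718729e-02
64.0,2.591865e-02
66.0,2.461646e-02
68.0,4.771300e-02
70.0,2.208346e-02
72.0,2.085658e-02
74.0,1.963916e-02
76.0,1.847133e-02
78.0,1.734907e-02
80.0,1.622610e-02
82.0,1.514694e-02
84.0,1.410878e-02
86.0,1.310446e-02
88.0,1.211737e-02
90.0,1.116663e-02
92.0,1.024982e-02
94.0,9.364703e-03
96.0,8.498293e-03
98.0,7.661605e-03
100.0,6.853062e-03
102.0,6.070976e-03
104.0,5.311914e-03
106.0,4.574165e-03
108.0,3.859867e-03
110.0,3.167724e-03
112.0,2.496532e-03
114.0,1.844770e-03
116.0,1.211522e-03
118.0,5.969124e-04
120.0,0.000000e+00
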