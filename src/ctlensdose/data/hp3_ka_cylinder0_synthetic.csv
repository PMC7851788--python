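energy_keV,value
10,0.42
15,0.89
20,1.19
25,1.38
30,1.50
40,1.63
50,1.67
60,1.64
80,1.55
100,1.47
125,1.40
150,1.35
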