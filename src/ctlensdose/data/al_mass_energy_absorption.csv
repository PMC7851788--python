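energy_keV,value
10,25.43
15,7.487
20,3.094
30,0.8778
40,0.3601
50,0.1840
60,0.1099
80,0.05511
100,0.03794
150,0.02827
200,0.02745
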