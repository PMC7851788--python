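energy_keV,value
10,230.0
15,139.0
20,65.73
30,22.73
40,10.67
50,5.949
60,3.713
69.5,2.552
69.55,11.23
80,7.810
100,4.438
150,1.581
200,0.708
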