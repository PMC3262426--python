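cL0 = 4.1
cL1 = 0.95
c0 = 12.0
c1 = 1.1
c2 = 0.24
c3 = -0.7
k12 = 0.09
k13 = 7.0
k23 = -0.1
Gmin = 33.0
Gmax = 42.0
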