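b1 = 53.96
b2 = 0.055
b3 = 24.82
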