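((A1:0.001,A2:0.002):0.1,(B1:0.001,B2:0.003):0.12,(C1:0.002,(C2:0.001,C3:0.001):0.001):0.11);
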