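(((a1:0.1,a2:0.1):5.1,(b1:0.15,b2:0.15):5.05):0.8,((c1:0.12,(c2:0.05,c3:0.05):0.07):4.88,(d1:0.2,d2:0.2):4.8):1.0);
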