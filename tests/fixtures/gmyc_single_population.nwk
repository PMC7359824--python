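((((a:1.0,b:1.0):2.0,c:3.0):1.5,(d:2.0,e:2.0):2.5):3.0,(f:4.0,(g:2.5,h:2.5):1.5):3.5);
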