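((((x1:1,x2:1)e:1,x3:1)c:1,x4:1)a:1,((x5:1,x6:1)d:1,x7:1)b:1);
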