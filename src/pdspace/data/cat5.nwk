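((((x1:1,x2:1)f:1,x3:1)g:1,x4:1)h:1,x5:1);
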