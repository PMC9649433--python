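element,radius
C,1.70
N,1.55
O,1.52
S,1.80
P,1.80
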