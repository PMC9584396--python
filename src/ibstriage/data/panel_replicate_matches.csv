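gene,replicate,x,y
SLC19A1,1,11,11
SLC19A1,2,11,11
PPARD,1,11,11
PPARD,2,10,11
PPARD,3,10,11
PPARD,4,10,11
PPARD,5,10,11
PPARD,6,10,11
TPH1,1,10,11
TPH1,2,9,11
TPH1,3,9,11
CD36,1,9,11
CD36,2,9,11
CD36,3,9,11
VIP,1,9,11
VIP,2,9,11
VIP,3,9,11
SERT,1,9,11
SERT,2,8,11
SERT,3,8,11
VSIG2,1,8,11
VSIG2,2,8,11
VSIG2,3,8,11
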