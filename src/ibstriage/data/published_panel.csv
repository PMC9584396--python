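gene,microarray_fold,qpcr_fold,percent_accuracy
SLC19A1,0.62,0.39,100
PPARD,0.70,0.50,92.42
TPH1,0.93,0.58,84.85
CD36,0.64,0.73,81.82
VIP,0.74,0.70,81.82
SERT,0.48,0.96,75.76
VSIG2,1.14,1.27,72.73
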