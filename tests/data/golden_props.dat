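1 5
1 0.016400 0.747475 0.010000 1.370000
2 0.011500 0.949495 0.010000 1.370000
3 0.002600 0.010101 0.010000 1.370000
4 0.018600 1.121212 0.010000 1.370000
5 0.018600 1.121212 0.010000 1.370000
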