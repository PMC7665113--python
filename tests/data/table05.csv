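waveIn,waveOut,fist,open,pinch,noGesture
7338,49,80,46,39,171
75,7460,65,54,29,134
22,13,7301,44,22,137
76,68,118,7381,123,139
31,40,43,36,7175,149
108,20,43,89,262,6920
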