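waveIn,waveOut,fist,open,pinch,noGesture
6651,138,336,302,725,217
207,6550,83,416,264,139
359,29,6614,262,656,160
147,849,391,6165,1034,162
95,30,126,295,4424,95
191,54,100,210,547,6877
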