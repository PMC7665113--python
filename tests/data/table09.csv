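waveIn,waveOut,fist,open,pinch,noGesture
6666,143,344,296,744,215
197,6482,85,370,260,139
341,39,6612,251,663,160
163,892,387,6257,1069,170
92,30,121,265,4373,87
191,64,101,211,541,6879
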