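waveIn,waveOut,fist,open,pinch,noGesture
6421,151,201,239,549,186
198,6544,112,516,270,134
467,26,6696,278,682,153
209,799,358,6070,891,170
160,79,173,395,4832,116
195,51,110,152,426,6891
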