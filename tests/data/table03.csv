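waveIn,waveOut,fist,open,pinch,noGesture
7339,65,73,57,36,168
86,7416,64,54,32,136
18,10,7305,43,19,136
79,94,100,7385,113,138
34,41,53,49,7232,150
94,24,55,62,218,6922
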