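waveIn,waveOut,fist,open,pinch,noGesture
7335,50,86,46,40,173
77,7471,59,50,28,134
27,10,7307,43,24,141
72,67,113,7386,125,137
33,35,41,33,7174,150
106,17,44,92,259,6915
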