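waveIn,waveOut,fist,open,pinch,noGesture
3490,3049,2426,2991,2986,413
1333,3007,561,488,189,100
1619,715,3437,1362,1775,203
341,645,561,2146,710,91
568,117,422,377,1594,81
299,117,243,286,396,6762
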