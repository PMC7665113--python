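waveIn,waveOut,fist,open,pinch,noGesture
4831,431,164,211,218,3
368,5370,262,682,406,3
1047,548,5361,1009,1588,29
334,458,404,4072,795,2
105,253,337,342,2437,3
965,590,1122,1334,2206,7610
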