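waveIn,waveOut,fist,open,pinch,noGesture
2961,2265,2104,2231,2155,291
1204,2320,970,1030,756,136
1763,1874,2862,1714,1579,254
515,526,594,1389,516,127
869,566,874,965,2052,143
338,99,246,321,592,6699
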