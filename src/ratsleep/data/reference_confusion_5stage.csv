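stage,W,N1,N2,TS,R
W,77822,1747,231,154,486
N1,3807,41452,1576,718,591
N2,499,1207,19663,5,60
TS,152,907,51,4013,206
R,156,175,24,191,12763
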