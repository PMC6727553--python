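stage,W,N,R
W,77822,2132,486
N,4458,69592,857
R,156,390,12763
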