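stage,Art,W,N1,N2,N3,REM
Art,70,13,21,14,0,14
W,84,714,85,133,3,103
N1,29,51,300,295,1,63
N2,63,11,96,3288,121,44
N3,6,3,1,241,1705,1
REM,35,14,75,126,0,1518
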