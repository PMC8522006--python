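stage,Art,W,N1,N2,N3,REM
Art,100,8,2,19,1,2
W,63,769,47,135,10,98
N1,27,86,257,306,3,60
N2,135,71,133,2958,244,82
N3,2,2,1,198,1753,1
REM,83,23,70,399,2,1191
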