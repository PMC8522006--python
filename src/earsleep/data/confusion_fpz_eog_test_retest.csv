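stage,Art,W,N1,N2,N3,REM
Art,63,19,1,1,0,5
W,4,927,96,18,2,8
N1,0,58,370,260,0,53
N2,0,117,168,2870,226,23
N3,1,7,2,39,1495,0
REM,0,102,91,104,1,1562
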