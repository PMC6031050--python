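A,B,C,D,fitness
0,0,0,0,1.0
1,0,0,0,1.1198587895539038
0,1,0,0,1.3202287396724548
1,1,0,0,1.4784697583438713
0,0,1,0,1.4972475898375799
1,0,1,0,1e-09
0,1,1,0,1.9767092985088888
1,1,1,0,2.2136352823281107
0,0,0,1,1e-09
1,0,0,1,1e-09
0,1,0,1,1e-09
1,1,0,1,1.6933297897856223
0,0,1,1,1e-09
1,0,1,1,1e-09
0,1,1,1,1e-09
1,1,1,1,2.5353339465566993
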