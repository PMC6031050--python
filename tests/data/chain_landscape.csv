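A,B,F,G,H,fitness
0,0,0,0,0,1.0
1,0,0,0,0,1.1178830002052786
0,1,0,0,0,1e-09
1,1,0,0,0,1.8861064570078412
0,0,1,0,0,1.656290170056803
1,0,1,0,0,1.8515386245136103
0,1,1,0,0,1e-09
1,1,1,0,0,3.123939584422751
0,0,0,1,0,1e-09
1,0,0,1,0,1e-09
0,1,0,1,0,1e-09
1,1,0,1,0,1e-09
0,0,1,1,0,2.280480835030478
1,0,1,1,0,2.5493107577745104
0,1,1,1,0,1e-09
1,1,1,1,0,4.301229628033618
0,0,0,0,1,1e-09
1,0,0,0,1,1e-09
0,1,0,0,1,1e-09
1,1,0,0,1,1e-09
0,0,1,0,1,1e-09
1,0,1,0,1,1e-09
0,1,1,0,1,1e-09
1,1,1,0,1,1e-09
0,0,0,1,1,1e-09
1,0,0,1,1,1e-09
0,1,0,1,1,1e-09
1,1,0,1,1,1e-09
0,0,1,1,1,3.5191483630917664
1,0,1,1,1,3.9339961303005198
0,1,1,1,1,1e-09
1,1,1,1,1,6.637488450795955
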