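species,lc,Fj,Fp,vM1,vM2,vM3,GV1,GV2,GV3,F,V_bone,V_ker
G. fortis,PB,11.9,10.9,21,19,29,0.83,0.98,0.81,30.4,104,128
G. fortis,PT,11.9,10.9,47,36,41,0.78,0.95,0.82,21.5,104,128
G. magnirostris,PB,23.0,21.9,35,24,40,0.86,0.97,0.77,57.9,232,195
G. magnirostris,PT,23.0,21.9,66,35,46,0.62,0.98,0.81,41.6,232,195
G. magnirostris,FB,11.9,10.9,22,16,26,0.86,0.97,0.77,29.3,157,131
G. magnirostris,FT,11.9,10.9,43,23,30,0.62,0.98,0.81,20.9,157,131
G. fuliginosa,PB,2.2,3.2,18,15,18,0.74,0.93,0.85,7.1,24,35
G. fuliginosa,PT,2.2,3.2,24,28,27,0.60,0.88,0.84,4.6,24,35
G. fuliginosa,FB,11.9,10.9,29,23,28,0.74,0.93,0.85,29.2,115,164
G. fuliginosa,FT,11.9,10.9,35,41,42,0.60,0.88,0.84,19.0,115,164
G. conirostris,PB,5.4,5.3,16,25,42,0.86,0.85,0.76,15.3,76,82
G. conirostris,PT,5.4,5.3,25,40,47,0.98,0.83,0.70,10.4,76,82
G. conirostris,FB,11.9,10.9,25,33,67,0.86,0.85,0.76,32.3,112,121
G. conirostris,FT,11.9,10.9,45,63,67,0.98,0.83,0.70,18.8,112,121
G. scandens,PB,3.2,4.5,20,15,23,0.67,0.92,0.74,8.9,59,56
G. scandens,PT,3.2,4.5,17,33,35,0.88,0.95,0.82,6.1,59,56
G. scandens,FB,11.9,10.9,40,28,43,0.67,0.92,0.74,26.2,126,119
G. scandens,FT,11.9,10.9,30,60,63,0.88,0.95,0.82,17.9,126,119
G. difficilis,PB,1.5,1.6,14,12,21,0.87,1.00,0.97,3.6,22,30
G. difficilis,PT,1.5,1.6,18,19,18,0.73,0.98,0.98,2.4,22,30
G. difficilis,FB,11.9,10.9,38,24,51,0.87,1.00,0.97,26.1,86,116
G. difficilis,FT,11.9,10.9,50,56,53,0.73,0.98,0.98,16.7,86,116
P. inornata,FB,11.9,10.9,55,32,59,0.66,0.95,0.85,26.2,109,96
P. inornata,FT,11.9,10.9,76,67,61,0.71,1.00,0.83,13.8,109,96
C. olivacea,PB,0.9,1.0,23,31,45,0.50,0.84,0.81,2.0,9,9
C. olivacea,PT,0.9,1.0,23,32,22,1.00,1.00,0.94,1.0,9,9
C. olivacea,FB,11.9,10.9,58,66,100,0.50,0.84,0.81,24.4,99,100
C. olivacea,FT,11.9,10.9,58,78,59,1.00,1.00,0.94,12.3,99,100
C. pallida,FB,11.9,10.9,59,33,80,0.77,0.71,0.88,25.4,68,101
C. pallida,FT,11.9,10.9,38,46,64,0.67,0.87,0.89,15.1,68,101
C. parvulus,PB,1.3,1.3,22,12,20,0.57,0.94,0.61,3.3,11,18
C. parvulus,PT,1.3,1.3,13,19,25,0.66,0.82,0.58,2.2,11,18
C. parvulus,FB,11.9,10.9,47,26,43,0.57,0.94,0.61,29.6,88,143
C. parvulus,FT,11.9,10.9,29,41,55,0.66,0.82,0.58,19.5,88,143
C. pauper,FB,11.9,10.9,23,17,37,0.60,0.94,0.52,31.2,118,163
C. pauper,FT,11.9,10.9,19,25,35,0.82,0.99,0.75,19.4,118,163
C. psittacula,FB,11.9,10.9,39,24,33,0.46,0.88,0.90,30.5,93,127
C. psittacula,FT,11.9,10.9,25,28,35,0.71,0.63,0.90,21.9,93,127
P. crassirostris,FB,11.9,10.9,21,21,31,0.84,0.93,0.81,32.1,138,152
P. crassirostris,FT,11.9,10.9,25,32,43,0.82,0.97,0.90,21.7,138,152
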