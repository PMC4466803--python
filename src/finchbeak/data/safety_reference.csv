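species,behavior,model_force_base,model_force_tip,sf_base,sf_tip
G. fortis,base_crush,30,22,1.6,1.0
G. magnirostris,base_crush,58,42,1.1,0.7
G. fuliginosa,base_crush,7.1,4.6,2.5,1.6
G. conirostris,probe_and_crush,15,10,1.1,1.0
G. scandens,probe_and_crush,8.9,6.1,2.0,1.3
G. difficilis,probe_and_crush,3.6,2.4,2.1,2.3
C. olivacea,probe,2.0,1.0,1.0,1.4
C. parvulus,tip_crush,3.4,2.2,2.1,1.8
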