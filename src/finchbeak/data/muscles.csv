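species,muscle,mass_g,fiber_length_mm,pathway
G. magnirostris,MDM,0.0522,3.99,none
G. magnirostris,MAMER,0.1813,2.31,indirect_jugal
G. magnirostris,MAMEV,0.0451,2.01,indirect_jugal
G. magnirostris,MAMEP,0.0595,2.02,indirect_jugal
G. magnirostris,MAMOQ,0.0084,2.58,indirect_jugal
G. magnirostris,MPsTSl,0.0137,1.36,indirect_jugal
G. magnirostris,MPsTSm,0.0624,1.39,indirect_jugal
G. magnirostris,MPsTP,0.0447,4.18,indirect_jugal
G. magnirostris,MPtVl,0.0752,2.58,direct_palatine
G. magnirostris,MPtVm,0.0758,2.56,direct_palatine
G. magnirostris,MPtDl,0.0568,2.56,direct_palatine
G. magnirostris,MPtDm,0.022,2.63,direct_palatine
G. magnirostris,MRPal,0.0104,2.61,direct_palatine
G. magnirostris,MPPtQ,0.0085,2.65,none
G. conirostris,MDM,0.0455,4.12,none
G. conirostris,MAMER,0.0389,2.55,indirect_jugal
G. conirostris,MAMEV,0.0178,2.93,indirect_jugal
G. conirostris,MAMEP,0.0262,2.37,indirect_jugal
G. conirostris,MAMOQ,0.0035,2.21,indirect_jugal
G. conirostris,MPsTSl,0.0033,1.81,indirect_jugal
G. conirostris,MPsTSm,0.0157,2.62,indirect_jugal
G. conirostris,MPsTP,0.0269,4.52,indirect_jugal
G. conirostris,MPtVl,0.0079,3.10,direct_palatine
G. conirostris,MPtVm,0.0253,3.20,direct_palatine
G. conirostris,MPtDl,0.0240,3.42,direct_palatine
G. conirostris,MPtDm,0.0093,2.65,direct_palatine
G. conirostris,MRPal,0.0044,2.73,direct_palatine
G. conirostris,MPPtQ,0.0086,2.63,none
G. difficilis,MDM,0.005,2.91,none
G. difficilis,MAMER,0.0102,1.67,indirect_jugal
G. difficilis,MAMEV,0.0025,2.01,indirect_jugal
G. difficilis,MAMEP,0.0044,1.72,indirect_jugal
G. difficilis,MAMOQ,0.0002,1.64,indirect_jugal
G. difficilis,MPsTSl,0.0006,1.53,indirect_jugal
G. difficilis,MPsTSm,0.0012,2.15,indirect_jugal
G. difficilis,MPsTP,0.0064,2.76,indirect_jugal
G. difficilis,MPtVl,0.0020,2.36,direct_palatine
G. difficilis,MPtVm,0.0055,4.32,direct_palatine
G. difficilis,MPtDl,0.0071,2.54,direct_palatine
G. difficilis,MPtDm,0.003,2.21,direct_palatine
G. difficilis,MRPal,0.0014,1.98,direct_palatine
G. difficilis,MPPtQ,0.0004,1.62,none
G. fuliginosa,MDM,0.0070,2.85,none
G. fuliginosa,MAMER,0.0163,2.13,indirect_jugal
G. fuliginosa,MAMEV,0.0035,1.41,indirect_jugal
G. fuliginosa,MAMEP,0.0069,1.46,indirect_jugal
G. fuliginosa,MAMOQ,0.0010,2.02,indirect_jugal
G. fuliginosa,MPsTSl,0.0020,1.12,indirect_jugal
G. fuliginosa,MPsTP,0.0020,1.46,indirect_jugal
G. fuliginosa,MPtVl,0.0027,2.09,direct_palatine
G. fuliginosa,MPtVm,0.0036,1.99,direct_palatine
G. fuliginosa,MPtDl,0.0052,1.69,direct_palatine
G. fuliginosa,MPtDm,0.0032,2.10,direct_palatine
G. fuliginosa,MRPal,0.0014,2.60,direct_palatine
G. fuliginosa,MPPtQ,0.0020,2.22,none
C. parvulus,MDM,0.0056,3.45,none
C. parvulus,MAMER,0.0130,3.07,indirect_jugal
C. parvulus,MAMEV,0.0029,2.11,indirect_jugal
C. parvulus,MAMEP,0.0065,1.92,indirect_jugal
C. parvulus,MAMOQ,0.0005,1.44,indirect_jugal
C. parvulus,MPsTSl,0.0013,1.67,indirect_jugal
C. parvulus,MPsTP,0.0022,1.58,indirect_jugal
C. parvulus,MPtVl,0.0044,2.81,direct_palatine
C. parvulus,MPtVm,0.0016,2.81,direct_palatine
C. parvulus,MPtDl,0.0027,3.19,direct_palatine
C. parvulus,MPtDm,0.0029,2.75,direct_palatine
C. parvulus,MRPal,0.0012,3.18,direct_palatine
C. parvulus,MPPtQ,0.0040,2.61,none
C. olivacea,MDM,0.0033,2.05,none
C. olivacea,MAMER,0.0041,1.74,indirect_jugal
C. olivacea,MAMEV,0.0011,1.14,indirect_jugal
C. olivacea,MAMEP,0.0022,1.33,indirect_jugal
C. olivacea,MPsTSl,0.0007,1.03,indirect_jugal
C. olivacea,MPsTP,0.0005,1.30,indirect_jugal
C. olivacea,MPtVl,0.0021,2.66,direct_palatine
C. olivacea,MPtVm,0.0014,2.27,direct_palatine
C. olivacea,MPtDl,0.0008,2.47,direct_palatine
C. olivacea,MPtDm,0.0016,1.86,direct_palatine
C. olivacea,MRPal,0.0004,1.80,direct_palatine
C. olivacea,MPPtQ,0.0019,1.86,none
G. scandens,MDM,0.015,3.89,none
G. scandens,MAMER,0.0329,2.52,indirect_jugal
G. scandens,MAMEV,0.009,1.89,indirect_jugal
G. scandens,MAMEP,0.0126,1.98,indirect_jugal
G. scandens,MAMOQ,0.0016,2.64,indirect_jugal
G. scandens,MPsTSl,0.0071,1.22,indirect_jugal
G. scandens,MPsTSm,0.0052,1.22,indirect_jugal
G. scandens,MPsTP,0.0168,1.54,indirect_jugal
G. scandens,MPtVl,0.0072,2.99,direct_palatine
G. scandens,MPtVm,0.0062,2.96,direct_palatine
G. scandens,MPtDl,0.0247,2.70,direct_palatine
G. scandens,MPtDm,0.0108,2.75,direct_palatine
G. scandens,MRPal,0.0057,2.60,direct_palatine
G. scandens,MPPtQ,0.0042,2.30,none
G. fortis,MDM,0.02,3.91,none
G. fortis,MAMER,0.0651,1.87,indirect_jugal
G. fortis,MAMEV,0.0159,1.85,indirect_jugal
G. fortis,MAMEP,0.0217,1.70,indirect_jugal
G. fortis,MAMOQ,0.0026,2.02,indirect_jugal
G. fortis,MPsTSl,0.0094,1.31,indirect_jugal
G. fortis,MPsTSm,0.0124,2.06,indirect_jugal
G. fortis,MPsTP,0.0283,3.58,indirect_jugal
G. fortis,MPtVl,0.0199,2.38,direct_palatine
G. fortis,MPtVm,0.0119,2.52,direct_palatine
G. fortis,MPtDl,0.0284,2.07,direct_palatine
G. fortis,MPtDm,0.0333,1.73,direct_palatine
G. fortis,MRPal,0.0041,2.88,direct_palatine
G. fortis,MPPtQ,0.0059,3.40,none
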