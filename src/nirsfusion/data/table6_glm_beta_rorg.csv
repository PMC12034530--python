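channel,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10,P11,P12
CH1,0.0293,-0.1053,-0.0245,0.0114,0.0237,-0.0352,0.0019,-0.0115,0.0181,0.0267,-0.0075,0.0372
CH2,-0.0106,-0.1013,0.0042,0.0056,-0.0003,-0.0061,0.0416,-0.0202,0.0270,-0.0520,0.0085,0.0389
CH3,-0.0117,-0.0883,0.0179,0.0168,0.0264,-0.0099,0.0377,-0.0182,-0.0123,0.0011,0.0081,0.0453
CH4,-0.0228,-0.0437,-0.0080,-0.0056,-0.0028,0.0085,-0.0176,-0.0326,0.0080,0.0693,-0.0014,0.0141
CH5,-0.0412,-0.1357,-0.0242,0.0809,-0.0102,-0.0145,0.0895,-0.0106,-0.0149,0.0627,-0.0269,-0.0025
CH6,-0.0051,-0.0889,-0.0425,0.0153,-0.0266,-0.0216,0.0102,-0.0523,0.0000,0.0913,-0.0003,0.0172
CH7,-0.0099,-0.0296,-0.0071,-0.0141,-0.0201,-0.0171,0.0323,-0.0429,-0.0069,0.0935,-0.0147,0.0082
CH8,0.0126,-0.0396,0.0013,-0.0138,0.0954,-0.0668,0.0138,-0.0030,-0.0055,0.0493,-0.0135,-0.0242
CH9,-0.0398,-0.0833,0.0202,-0.0141,-0.0338,-0.0173,-0.0230,-0.0010,0.0035,0.0291,-0.0169,-0.0286
CH10,-0.0031,-0.0394,0.0062,0.0061,-0.0125,-0.0129,0.0257,-0.0342,-0.0024,0.0425,0.0044,0.0164
CH11,0.0011,-0.0592,-0.0283,-0.0032,-0.0133,-0.0272,0.0150,-0.0160,-0.0014,-0.0165,-0.0191,0.0117
CH12,-0.0312,-0.0206,-0.0050,-0.0203,-0.0094,-0.0236,-0.0160,-0.0214,0.0389,0.0713,0.0010,-0.0086
CH13,-0.0022,-0.0452,-0.0076,0.0028,-0.0099,-0.0360,0.0008,0.0028,-0.0155,-0.0370,-0.0092,-0.0070
CH14,-0.0043,-0.0193,-0.0132,0.0012,-0.0200,-0.0405,0.0090,-0.0171,-0.0039,0.0527,-0.0295,0.0021
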