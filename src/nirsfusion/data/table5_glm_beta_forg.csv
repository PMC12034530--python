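channel,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10,P11,P12
CH1,-0.0210,0.1377,-0.0260,0.0237,-0.0139,-0.0131,-0.0200,0.0608,-0.0001,-0.0263,0.0119,-0.0052
CH2,0.0024,0.1003,-0.0726,0.0285,0.0023,-0.0118,-0.0335,0.0421,0.0223,0.0033,-0.0046,0.0130
CH3,-0.0339,0.0924,-0.0601,-0.0018,-0.0118,-0.0050,-0.0843,0.0582,-0.0065,-0.0452,0.0138,0.0201
CH4,-0.0226,0.0403,-0.0101,0.0187,-0.0091,-0.0096,-0.0538,0.0340,0.0558,-0.0690,-0.0155,0.0105
CH5,-0.0131,0.0751,-0.0109,-0.0151,-0.0111,-0.0164,0.0237,0.0650,-0.0462,-0.0171,0.0137,0.0830
CH6,-0.0211,0.0509,-0.0026,0.0407,-0.0226,0.0101,-0.0573,0.0239,-0.0047,-0.0707,0.0109,0.0810
CH7,-0.0128,0.0414,-0.0377,0.0354,-0.0195,-0.0141,-0.0137,0.0448,-0.0007,-0.0765,0.0062,0.0081
CH8,-0.0286,0.0358,-0.0368,0.0242,-0.0709,0.0265,-0.0505,-0.0057,-0.0073,-0.0745,0.0159,0.0103
CH9,-0.0170,0.1274,-0.0963,0.0122,-0.0184,0.0048,0.0740,-0.0039,-0.0681,-0.0566,0.0017,0.0196
CH10,-0.0020,0.0711,-0.0392,0.0089,-0.0014,-0.0033,0.0038,0.0462,0.0022,-0.0851,-0.0036,0.0244
CH11,-0.0346,0.0613,-0.0411,0.0143,0.0069,-0.0013,-0.0022,0.0259,-0.0102,-0.0148,0.0152,-0.0163
CH12,0.0007,0.0354,0.0282,0.0350,0.0015,0.0104,-0.0057,0.0527,0.0351,0.0638,0.0100,0.0055
CH13,0.0045,0.0591,0.0392,0.0128,0.0005,0.0283,-0.0001,0.0437,0.0119,0.0297,0.0301,0.0247
CH14,0.0087,0.0412,0.0036,0.0063,0.0099,0.0004,0.0254,0.0238,0.0451,0.0511,0.0289,0.0085
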