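participant,midgray,forg,rorg
P1,0.0999,0.1405,0.1086
P2,0.1804,0.2160,0.1878
P3,0.2320,0.5795,0.4877
P4,0.1544,0.1829,0.1694
P5,0.0912,0.3045,0.1080
P6,0.2414,0.6541,0.4195
P7,0.0060,0.0688,0.0542
P8,0.2210,0.3919,0.3371
P9,0.1517,0.3795,0.2678
P10,0.1056,0.4671,0.2423
P11,0.1686,0.2712,0.1926
P12,0.1498,0.3239,0.2938
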