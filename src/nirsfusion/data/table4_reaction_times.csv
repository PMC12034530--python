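participant,rt1,rt2,rt3,rt4,rt5,rt6,rt7,rt8,mean_rt,sd_rt
P1,6.5,1.0,2.5,1.1,0.9,0.8,0.8,1.1,1.84,1.96
P2,1.2,1.0,1.0,1.2,1.3,1.2,1.1,1.0,1.13,0.12
P3,0.8,0.7,0.7,1.7,0.9,1.0,0.7,0.9,0.93,0.33
P4,8.7,3.9,3.4,2.8,2.0,4.0,2.4,3.1,3.79,2.10
P5,2.7,2.2,5.6,2.8,4.4,2.5,2.8,2.3,3.16,1.20
P6,7.4,3.4,1.8,0.9,1.4,3.0,4.7,1.0,2.95,2.23
P7,2.9,6.8,3.6,8.6,5.9,7.5,6.8,3.0,5.64,2.19
P8,1.3,0.9,0.8,1.0,0.8,0.9,1.1,1.0,0.98,0.17
P9,1.5,1.2,1.3,1.1,1.0,1.8,1.4,1.0,1.29,0.25
P10,2.4,1.3,1.5,1.0,1.9,2.0,1.8,2.6,1.81,0.43
P11,1.2,1.1,1.2,1.0,1.5,0.9,1.3,1.6,1.23,0.25
P12,3.2,3.0,2.8,2.5,2.6,2.5,2.8,2.6,2.75,0.23
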