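channel,statistic,corrected_p,significant
CH1,35,0.92285,No
CH2,38,0.96973,No
CH3,27,0.88563,No
CH4,38,0.96973,No
CH5,35,0.92285,No
CH6,27,0.88563,No
CH7,31,0.88563,No
CH8,31,0.88563,No
CH9,29,0.88563,No
CH10,33.5,0.92285,No
CH11,27,0.88563,No
CH12,3,0.01139,Yes
CH13,1,0.00684,Yes
CH14,1,0.00684,Yes
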