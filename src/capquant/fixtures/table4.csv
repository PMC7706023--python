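patient,oct_t1,oct_t2,ivus_t1,ivus_t2
P1,3,3,2,2
P2,2,3,2,2
P3,3,1,3,2
P4,1,1,3,3
P5,2,3,3,2
P6,2,1,4,4
P7,1,1,3,2
P8,3,3,4,3
P9,3,2,3,3
P10,1,1,3,1
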