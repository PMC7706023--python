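oct_index,n_slices,ivus_1,ivus_2,ivus_3,ivus_4
1,300,225,50,23,2
2,33,22,3,7,1
3,15,4,8,3,0
4,0,0,0,0,0
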