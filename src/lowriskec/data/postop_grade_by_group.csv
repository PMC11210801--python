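preop_group,g1,g2,g3,inadequate
group1,88,13,2,3
group2,16,20,2,3
group3,64,10,0,0
group4,9,20,1,0
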