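preop_group,group1,group2,group3,group4,higher
group1,46,6,38,5,11
group2,4,6,11,10,10
group3,14,0,45,9,6
group4,3,2,4,13,8
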