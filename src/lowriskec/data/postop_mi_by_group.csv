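preop_group,none,lt_half,ge_half
group1,57,46,3
group2,14,26,1
group3,14,55,5
group4,6,20,4
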