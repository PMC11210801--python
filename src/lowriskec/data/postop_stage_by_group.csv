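preop_group,ia,ib,ii,iiia,iiib,iiic,iv
group1,100,3,0,0,0,3,0
group2,36,0,2,0,0,3,0
group3,68,5,1,0,0,0,0
group4,23,4,3,0,0,0,0
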