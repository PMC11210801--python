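key,value
n_total,251
n_group1,106
n_group2,41
n_group3,74
n_group4,30
age_mean,52.8
age_sd,9.6
menopause_prob,0.606
biopsy_d_and_c_prob,0.908
biopsy_hysteroscopy_prob,0.024
biopsy_pipelle_prob,0.068
preop_size_missing_prob,0.355
ca125_mean,19.2
ca125_sd,10.1
postop_size_mean_mi_none_cm,1.41
postop_size_mean_mi_lt_half_cm,2.45
postop_size_mean_mi_ge_half_cm,2.95
surgery_mis_prob,0.861
lvsi_prob,0.088
endometrioid_prob,0.988
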