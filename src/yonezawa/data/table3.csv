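study,source_table,tissue,endpoint,d1_gy,d2_gy,dt_h,t_h,n2_events,n2_denom,n12_events,n12_denom,delta,footnote
day_etal_1,-,prostate,chromosomal_inversions,0.000001,1,4,72,0.00572,1,0.00093,1,0.837,
day_etal_1,-,prostate,chromosomal_inversions,0.00001,1,4,72,0.00572,1,0.00170,1,0.703,
day_etal_1,-,prostate,chromosomal_inversions,0.001,1,4,72,0.00572,1,0.00188,1,0.671,
day_etal_1,-,prostate,chromosomal_inversions,0.01,1,4,72,0.00572,1,0.00098,1,0.829,
day_etal_2,-,prostate,chromosomal_inversions,0.00001,1,4,72,0.00466,1,0.00088,1,0.811,
day_etal_2,-,prostate,chromosomal_inversions,0.01,1,4,72,0.00466,1,0.00113,1,0.758,
day_etal_2,-,spleen,chromosomal_inversions,0.00001,1,4,72,0.00315,1,0.00077,1,0.756,
day_etal_2,-,spleen,chromosomal_inversions,0.01,1,4,72,0.00315,1,0.00098,1,0.689,
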