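region,non_normal,all_mean,all_sd,cv_rms,oa_central,oa_sd,normal_central,normal_sd,difference_absolute,difference_percent,ci_low,ci_high,p_value,cohens_d
Medial compartment,0,7708,2986,3.6,8515,3767,6902,2190,1613,23.4,-1862,5088,0.332,0.54
Lateral compartment,0,5959,1545,5.0,6200,1201,5718,1896,482,8.4,-1366,2331,0.58,0.31
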