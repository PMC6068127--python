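region,non_normal,all_mean,all_sd,cv_rms,oa_central,oa_sd,normal_central,normal_sd,difference_absolute,difference_percent,ci_low,ci_high,p_value,cohens_d
Medial peripheral cortical,1,-0.36,0.19,5.7,-0.51,0.18,-0.22,0.08,-0.25,-115.3,-0.36,-0.11,0.006,1.36
Medial epiphyseal cortical,0,-0.59,0.31,6.6,-0.8,0.28,-0.38,0.17,-0.41,-107.2,-0.68,-0.14,0.006,1.33
Medial metaphyseal cortical,1,-2.06,0.88,7.7,-2.56,0.95,-1.38,0.27,-1.18,-85.2,-1.71,-0.22,0.013,1.28
Medial subchondral cortical,1,-0.52,0.16,3.9,-0.63,0.18,-0.41,0.06,-0.17,-41.7,-0.35,-0.02,0.018,1.22
Medial subchondral trabecular,1,-0.46,0.15,3.7,-0.51,0.17,-0.37,0.06,-0.15,-41.1,-0.33,-0.01,0.035,1.13
Medial epiphyseal trabecular,1,-0.43,0.15,4.8,-0.47,0.18,-0.35,0.06,-0.12,-33.2,-0.32,0.01,0.085,1.03
Medial metaphyseal trabecular,1,-0.51,0.26,8.9,-0.55,0.3,-0.34,0.1,-0.21,-63.0,-0.41,0.01,0.064,1.01
Subchondral spine,0,-0.3,0.1,5.3,-0.37,0.07,-0.24,0.08,-0.14,-56.9,-0.22,-0.05,0.005,1.35
Epiphyseal central,0,-0.14,0.06,8.2,-0.16,0.03,-0.14,0.07,-0.02,-12.3,-0.08,0.05,0.559,0.33
Metaphyseal central,0,-0.12,0.04,7.3,-0.13,0.03,-0.12,0.05,-0.01,-3.8,-0.05,0.04,0.838,0.12
Lateral subchondral cortical,0,-0.32,0.09,5.0,-0.35,0.11,-0.29,0.06,-0.07,-22.8,-0.17,0.03,0.175,0.74
Lateral subchondral trabecular,0,-0.25,0.07,4.6,-0.26,0.08,-0.25,0.06,-0.02,-6.3,-0.1,0.07,0.698,0.22
Lateral epiphyseal trabecular,0,-0.19,0.05,5.3,-0.2,0.06,-0.19,0.05,-0.01,-3.0,-0.07,0.06,0.847,0.11
Lateral metaphyseal trabecular,0,-0.15,0.04,10.5,-0.15,0.04,-0.16,0.06,0.0,-2.2,-0.05,0.06,0.896,0.07
Lateral peripheral cortical,0,-0.22,0.05,5.2,-0.24,0.05,-0.2,0.04,-0.04,-22.4,-0.1,0.01,0.104,0.87
Lateral epiphyseal cortical,0,-0.25,0.06,5.9,-0.29,0.06,-0.23,0.04,-0.06,-25.2,-0.12,0.0,0.057,1.0
Lateral metaphyseal cortical,0,-0.7,0.21,5.2,-0.76,0.25,-0.65,0.17,-0.11,-17.1,-0.36,0.14,0.346,0.53
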