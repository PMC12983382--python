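outcome,variable,level,n,mean,sd
til_percent,age_group,<=30,3,11.14,2.74
til_percent,age_group,31-40,10,16.39,11.69
til_percent,age_group,41-50,14,24.34,14.11
til_percent,age_group,51-60,13,16.77,6.28
til_percent,age_group,>60,18,31.18,11.82
til_percent,gender,male,48,23.60,13.47
til_percent,gender,female,10,18.45,7.57
til_percent,site,lateral_tongue,29,22.37,12.86
til_percent,site,upper_alveolus_gingiva,2,23.92,8.97
til_percent,site,lower_alveolus_gingiva,7,24.90,16.56
til_percent,site,retromolar,1,7.88,0
til_percent,site,buccal_mucosa,18,22.27,11.93
til_percent,site,hard_palate,1,37.69,0
til_percent,p_stage,1,2,12.47,10.42
til_percent,p_stage,2,10,22.16,14.75
til_percent,p_stage,3,18,25.19,12.19
til_percent,p_stage,4,28,22.05,12.68
til_percent,p_n,N0,21,26.65,13.75
til_percent,p_n,N1,19,23.88,12.83
til_percent,p_n,N2,8,13.92,5.58
til_percent,p_n,N3,10,19.27,11.64
til_percent,c_stage,1,1,19.84,0
til_percent,c_stage,2,10,27.43,15.05
til_percent,c_stage,3,29,22.34,12.71
til_percent,c_stage,4,18,20.86,11.91
til_percent,c_n,N0,26,25.65,13.42
til_percent,c_n,N1,22,21.04,12.511
til_percent,c_n,N2,7,17.02,10.417
til_percent,c_n,N3,3,22.83,12.58
til_percent,grade,well,13,26.28,13.80
til_percent,grade,moderate,36,21.35,12.25
til_percent,grade,poor,9,23.01,13.70
doi,age_group,<=30,3,1.10,0.20
doi,age_group,31-40,10,1.32,0.48
doi,age_group,41-50,12,0.73,0.34
doi,age_group,51-60,12,1.38,1.05
doi,age_group,>60,18,1.13,0.58
doi,gender,male,46,1.15,0.70
doi,gender,female,9,1.01,0.53
doi,site,lateral_tongue,28,1.13,0.56
doi,site,upper_alveolus_gingiva,2,0.75,0.35
doi,site,lower_alveolus_gingiva,7,1.37,0.76
doi,site,retromolar,1,4.00,0
doi,site,buccal_mucosa,16,0.89,0.39
doi,site,hard_palate,1,1.20,0
doi,p_stage,1,2,1.05,0.49
doi,p_stage,2,10,0.77,0.30
doi,p_stage,3,17,0.96,0.40
doi,p_stage,4,26,1.39,0.83
doi,p_n,N0,20,0.79,0.30
doi,p_n,N1,18,1.17,0.58
doi,p_n,N2,8,1.78,1.13
doi,p_n,N3,9,1.23,0.50
doi,c_stage,1,1,0.70,0
doi,c_stage,2,10,0.73,0.25
doi,c_stage,3,27,1.27,0.59
doi,c_stage,4,17,1.17,0.87
doi,c_n,N0,24,1.07,0.78
doi,c_n,N1,21,1.28,0.65
doi,c_n,N2,7,0.97,0.40
doi,c_n,N3,3,0.96,0.11
doi,grade,well,13,0.89,0.39
doi,grade,moderate,34,1.24,0.79
doi,grade,poor,8,1.05,0.32
doi,bg_risk,low,37,0.98,0.59
doi,bg_risk,high,18,1.43,0.74
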