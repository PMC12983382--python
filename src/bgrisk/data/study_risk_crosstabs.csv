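variable,level,low_risk,high_risk
age_group,<=30,1,2
age_group,31-40,6,4
age_group,41-50,10,4
age_group,51-60,10,3
age_group,>60,12,6
gender,male,30,18
gender,female,9,1
site,lateral_tongue,22,7
site,upper_alveolus_gingiva,1,1
site,lower_alveolus_gingiva,4,3
site,retromolar,0,1
site,buccal_mucosa,11,7
site,hard_palate,1,0
p_stage,1,1,1
p_stage,2,9,1
p_stage,3,14,4
p_stage,4,15,13
p_n,N0,18,3
p_n,N1,13,6
p_n,N2,5,3
p_n,N3,3,7
c_stage,1,1,0
c_stage,2,10,0
c_stage,3,18,11
c_stage,4,10,8
c_n,N0,21,5
c_n,N1,14,8
c_n,N2,3,4
c_n,N3,1,2
grade,well,12,1
grade,moderate,20,16
grade,poor,7,2
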