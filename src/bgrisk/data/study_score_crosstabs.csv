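variable,level,score0,score1,score2,score3
age_group,<=30,0,1,1,1
age_group,31-40,2,4,1,3
age_group,41-50,4,6,4,0
age_group,51-60,4,6,0,3
age_group,>60,9,3,5,1
gender,male,15,15,10,8
gender,female,4,5,1,0
site,lateral_tongue,10,12,5,2
site,upper_alveolus_gingiva,0,1,1,0
site,lower_alveolus_gingiva,3,1,1,2
site,retromolar,0,0,0,1
site,buccal_mucosa,5,6,4,3
site,hard_palate,1,0,0,0
p_stage,1,1,0,0,1
p_stage,2,5,4,1,0
p_stage,3,7,7,3,1
p_stage,4,6,9,7,6
p_n,N0,9,9,2,1
p_n,N1,7,6,4,2
p_n,N2,1,4,1,2
p_n,N3,2,1,4,3
c_stage,1,1,0,0,0
c_stage,2,7,3,0,0
c_stage,3,8,10,5,6
c_stage,4,3,7,6,2
c_n,N0,12,9,2,3
c_n,N1,5,9,4,4
c_n,N2,1,2,3,1
c_n,N3,1,0,2,0
grade,well,9,3,1,0
grade,moderate,8,12,8,8
grade,poor,2,5,2,0
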