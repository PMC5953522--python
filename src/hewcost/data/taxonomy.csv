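id,display_name,group,urban_billable,rural_billable,sort_order
hygiene,Hygiene and environmental sanitation education/services,hygiene_environment,1,1,10
contraceptives,Provide contraceptives,family_health,1,1,20
anc_pnc,Provide antenatal and postnatal care,family_health,1,1,30
child_care,Provide care for sick and healthy children (including newborn),family_health,1,1,40
vaccinations,Provide vaccinations,family_health,1,1,50
nutrition,Provide nutrition education/services,family_health,1,1,60
other_health_education,Provide other health education,family_health,1,1,70
hiv_education,Provide education/services on HIV/AIDS,disease_prevention,1,1,80
vct_hiv,Provide voluntary counseling and testing on HIV,disease_prevention,0,1,90
malaria,"Test, educate and provide malaria treatment",disease_prevention,1,1,100
first_aid,First-aid education and referral,first_aid,1,1,110
tb_services,Provide TB related services,disease_prevention,0,1,120
ncd,Screening and education for non-communicable diseases,ncd,1,1,130
group_training,"Group training (ie, Women's Development Army)",group_training,1,1,140
travel,Travel,non_billable,0,0,900
recordkeeping,Recordkeeping and recording,non_billable,0,0,910
training_received,Receiving training and supervision,non_billable,0,0,920
idle,Idle or waiting time,non_billable,0,0,930
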