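raw_label,category_id
hygiene and environmental sanitation education/services,hygiene
hygiene and environmental sanitation,hygiene
environmental sanitation,hygiene
hygiene education,hygiene
provide contraceptives,contraceptives
contraceptives,contraceptives
family planning counseling,contraceptives
provide antenatal and postnatal care,anc_pnc
antenatal care,anc_pnc
postnatal care,anc_pnc
anc/pnc,anc_pnc
provide care for sick and healthy children (including newborn),child_care
provide care for sick and healthy children (includes newborn),child_care
child care,child_care
newborn care,child_care
sick child visit,child_care
provide vaccinations,vaccinations
vaccinations (includes tt and child),vaccinations
vaccination,vaccinations
immunization,vaccinations
provide nutrition education/services,nutrition
nutrition education,nutrition
nutrition services,nutrition
provide other health education,other_health_education
provide health education (education not covered elsewhere),other_health_education
health education,other_health_education
provide education/services on hiv/aids,hiv_education
hiv/aids education,hiv_education
hiv education,hiv_education
provide voluntary counseling and testing on hiv,vct_hiv
provide voluntary counseling & testing on hiv,vct_hiv
vct,vct_hiv
hiv testing and counseling,vct_hiv
"test, educate and provide malaria treatment",malaria
malaria treatment,malaria
malaria testing,malaria
first-aid education and referral,first_aid
provide first-aid (includes education and referral),first_aid
first aid,first_aid
first-aid,first_aid
provide tb related services,tb_services
tb services,tb_services
tuberculosis services,tb_services
screening and education for non-communicable diseases,ncd
non-communicable diseases,ncd
ncd screening,ncd
"group training (ie, women's development army)",group_training
extended trainings (women's development army),group_training
women's development army training,group_training
group training,group_training
travel,travel
walking between households,travel
recordkeeping and recording,recordkeeping
recordkeeping,recordkeeping
recording,recordkeeping
paperwork,recordkeeping
receiving training and supervision,training_received
training received,training_received
supervision received,training_received
idle,idle
waiting,idle
idle or waiting time,idle
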