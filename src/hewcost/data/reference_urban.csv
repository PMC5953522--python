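category_id,pct_encounters,mean_min,sd_min,base_birr,base_usd,cost82_birr,cost82_usd,cost270_birr,cost270_usd
hygiene,47.1,8.8,10.6,16.6,0.75,30.2,1.37,61.4,2.79
contraceptives,1.5,10.7,3.5,20.2,0.92,36.8,1.67,74.7,3.40
anc_pnc,4.7,9.3,8.2,17.6,0.80,32.0,1.45,65.1,2.96
child_care,1.1,14.8,19.7,27.9,1.27,50.8,2.31,103.2,4.69
vaccinations,6.6,29.2,29.2,55.1,2.50,100.3,4.56,203.9,9.27
nutrition,6.4,29.9,29.3,56.5,2.57,102.8,4.67,209.1,9.50
other_health_education,13.9,15.0,14.9,28.3,1.29,51.5,2.34,104.7,4.76
hiv_education,1.9,25.8,13.4,48.7,2.21,88.6,4.03,180.2,8.19
malaria,8.3,7.9,6.6,14.9,0.68,27.1,1.23,55.1,2.50
first_aid,1.1,12.8,9.1,24.2,1.10,44.0,2.00,89.5,4.07
ncd,5.5,13.3,11.3,25.1,1.14,45.7,2.08,92.9,4.22
group_training,1.9,52.7,64.7,99.5,4.52,181.1,8.23,368.2,16.74
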