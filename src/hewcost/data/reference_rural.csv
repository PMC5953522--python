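category_id,pct_encounters,mean_min,sd_min,base_birr,base_usd,cost82_birr,cost82_usd,cost270_birr,cost270_usd
hygiene,25.4,12.9,17.5,16.2,0.74,29.5,1.34,59.9,2.72
contraceptives,14.2,7.9,6.7,9.9,0.45,18.0,0.82,36.6,1.66
anc_pnc,6.3,20.5,18.6,25.7,1.17,46.8,2.13,95.1,4.32
child_care,5.8,15.9,11.6,19.9,0.90,36.2,1.65,73.6,3.35
vaccinations,15.4,11.3,11.5,14.2,0.65,25.8,1.17,52.5,2.39
nutrition,5.9,18.1,21.2,22.7,1.03,41.3,1.88,84.0,3.82
other_health_education,10.4,14.1,17.1,17.7,0.80,32.2,1.46,65.5,2.98
hiv_education,0.8,27.8,41.4,34.9,1.59,63.5,2.89,129.1,5.87
vct_hiv,0.2,47.3,18.6,59.3,2.70,107.9,4.90,219.4,9.97
malaria,10.1,16.6,10.3,20.8,0.95,37.9,1.72,77.0,3.50
first_aid,1.4,9.2,7.4,11.5,0.52,20.9,0.95,42.6,1.94
tb_services,1.9,4.2,2.4,5.3,0.24,9.6,0.44,19.6,0.89
ncd,1.3,6.1,5.4,7.7,0.35,14.0,0.64,28.5,1.30
group_training,1.0,99.3,77.0,124.5,5.66,226.6,10.30,460.7,20.94
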