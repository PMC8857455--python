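source,study,n,mean_d13C,sd_d13C,mean_d15N,sd_d15N,cn_ratio
MPB,survey_b,36,-16.6,1.9,5.8,0.7,8.1
surface_sediment,current,9,-19.5,1.0,6.8,0.7,9.8
surface_sediment,survey_a,32,-19.2,2.6,7.7,1.7,9.8
surface_sediment,survey_b,55,-20.1,0.9,5.6,0.7,9.8
polychaetes,current,2,-11.2,,11.5,,5.1
polychaetes,survey_a,2,-14.9,,14.0,,5.1
polychaetes,survey_b,18,-15.0,1.5,12.1,1.1,5.1
polychaetes,survey_b_nereis,13,-15.5,1.6,11.7,1.1,5.1
small_invertebrates,survey_b,5,-11.7,1.0,8.4,1.1,5.1
gastropods,current,5,-13.1,2.7,9.4,1.4,
bivalves,current,4,-11.0,1.2,9.2,1.0,
crabs,current,3,-14.0,0.6,8.2,0.1,
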