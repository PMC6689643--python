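landmark,x,y,z
infradentale,0.0,38.0,12.0
mandibular_orale,0.0,33.0,10.0
superior_transverse_torus,0.0,31.0,6.0
gnathion,0.0,36.0,-6.0
mental_foramen_l,8.0,30.0,2.0
p3_p4_lateral_l,9.0,26.0,9.0
m1_m2_lateral_l,11.0,18.0,9.0
m3_lateral_posterior_l,13.0,9.0,9.0
ramus_anterior_alveolus_l,16.0,4.0,10.0
gonion_l,20.0,-16.0,-8.0
ramus_posterior_alveolus_l,21.0,-12.0,10.0
condylion_laterale_l,22.0,-14.0,26.0
sigmoid_notch_l,17.0,-6.0,22.0
coronion_l,14.0,0.0,28.0
condylion_mediale_l,16.0,-15.0,26.0
mandibular_foramen_superior_l,14.0,-8.0,8.0
mental_foramen_r,-8.0,30.0,2.0
p3_p4_lateral_r,-9.0,26.0,9.0
m1_m2_lateral_r,-11.0,18.0,9.0
m3_lateral_posterior_r,-13.0,9.0,9.0
ramus_anterior_alveolus_r,-16.0,4.0,10.0
gonion_r,-20.0,-16.0,-8.0
ramus_posterior_alveolus_r,-21.0,-12.0,10.0
condylion_laterale_r,-22.0,-14.0,26.0
sigmoid_notch_r,-17.0,-6.0,22.0
coronion_r,-14.0,0.0,28.0
condylion_mediale_r,-16.0,-15.0,26.0
mandibular_foramen_superior_r,-14.0,-8.0,8.0
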