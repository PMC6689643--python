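# 28-landmark macaque mandible scheme: 4 midline landmarks on the sagittal
# plane and 12 bilateral (left/right) pairs.  Indices are 0-based positions
# in the `names` list.
dimension: 3
names:
  - infradentale
  - mandibular_orale
  - superior_transverse_torus
  - gnathion
  - mental_foramen_l
  - p3_p4_lateral_l
  - m1_m2_lateral_l
  - m3_lateral_posterior_l
  - ramus_anterior_alveolus_l
  - gonion_l
  - ramus_posterior_alveolus_l
  - condylion_laterale_l
  - sigmoid_notch_l
  - coronion_l
  - condylion_mediale_l
  - mandibular_foramen_superior_l
  - mental_foramen_r
  - p3_p4_lateral_r
  - m1_m2_lateral_r
  - m3_lateral_posterior_r
  - ramus_anterior_alveolus_r
  - gonion_r
  - ramus_posterior_alveolus_r
  - condylion_laterale_r
  - sigmoid_notch_r
  - coronion_r
  - condylion_mediale_r
  - mandibular_foramen_superior_r
midline: [0, 1, 2, 3]
pairs:
  - [4, 16]
  - [5, 17]
  - [6, 18]
  - [7, 19]
  - [8, 20]
  - [9, 21]
  - [10, 22]
  - [11, 23]
  - [12, 24]
  - [13, 25]
  - [14, 26]
  - [15, 27]
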