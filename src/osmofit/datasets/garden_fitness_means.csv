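population,treatment,trait,n_boxes,mean,se
FW,0,survival,10,0.49,0.03
FW,0,survival_male,10,0.33,0.03
FW,0,survival_female,10,0.16,0.04
FW,0,fecundity,10,77.90,15.54
FW,0,oviposition_rate,10,2.60,0.52
FW,0,n_immatures,10,28.00,6.23
FW,1,survival,8,0.19,0.05
FW,1,survival_male,8,0.14,0.04
FW,1,survival_female,8,0.05,0.02
FW,1,fecundity,8,21.00,10.75
FW,1,oviposition_rate,8,0.70,0.36
FW,1,n_immatures,8,5.63,1.45
FW,3,survival,8,0.16,0.04
FW,3,survival_male,8,0.15,0.04
FW,3,survival_female,8,0.01,0.01
FW,3,fecundity,8,0.88,0.40
FW,3,oviposition_rate,8,0.03,0.01
FW,3,n_immatures,8,0.63,0.32
FW,5,survival,8,0.14,0.05
FW,5,survival_male,8,0.11,0.04
FW,5,survival_female,8,0.03,0.02
FW,5,fecundity,8,12.00,5.14
FW,5,oviposition_rate,8,0.40,0.17
FW,5,n_immatures,8,1.00,0.57
BW,0,survival,8,0.35,0.04
BW,0,survival_male,8,0.24,0.05
BW,0,survival_female,8,0.11,0.04
BW,0,fecundity,8,24.00,4.50
BW,0,oviposition_rate,8,0.77,0.15
BW,0,n_immatures,8,8.00,2.83
BW,1,survival,8,0.31,0.15
BW,1,survival_male,8,0.20,0.03
BW,1,survival_female,8,0.11,0.04
BW,1,fecundity,8,17.00,4.13
BW,1,oviposition_rate,8,0.57,0.14
BW,1,n_immatures,8,3.63,1.05
BW,3,survival,8,0.29,0.04
BW,3,survival_male,8,0.25,0.04
BW,3,survival_female,8,0.04,0.01
BW,3,fecundity,8,18.00,4.54
BW,3,oviposition_rate,8,0.60,0.14
BW,3,n_immatures,8,4.63,1.13
BW,5,survival,8,0.24,0.05
BW,5,survival_male,8,0.13,0.05
BW,5,survival_female,8,0.11,0.05
BW,5,fecundity,8,18.50,5.02
BW,5,oviposition_rate,8,0.61,0.17
BW,5,n_immatures,8,2.50,0.87
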