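Case no.,Age(yrs),Sex,Tumor location,Tumor size(cm^3),MIB-1%,Percentage decrease in tract count
M1,68,M,RH premotor motor,11.67,2,10.41%
M2,55,M,LH parietal motor,52.99,2,21.25%
M3,48,F,LH temporal parietal motor,36.16,4,10.00%
M4,27,F,RH temporal motor premotor,106.25,4,32.00%
M5,35,M,LH premotor motor,43.03,10,15.10%
LGG1,28,F,LH insular temporal,107.4,3,45.10%
LGG2,37,F,RH frontal,13.29,4,24.68%
LGG3,37,F,LH frontal premotor,53.38,4,28.72%
LGG4,38,M,LH frontal premotor,98.83,4,81.25%
LGG5,46,M,LH temporal occipital insular,43.2,9,81.81%
LGG6,50,M,RH insular temporal parietal,46.15,9,81.85%
LGG7,40,M,RH premotor,11.16,35,89.92%
HGG1,41,F,RH temporal motor parietal,45.53,12,95.58%
HGG2,51,F,RH frontal premotor motor,46.62,18,96.18%
HGG3,32,M,LH frontal premotor,21.8,25,90.43%
HGG4,49,M,LH premotor motor insular,43.02,30,91.95%
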