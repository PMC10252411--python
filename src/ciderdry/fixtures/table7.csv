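sample_id,nyca_rating,sensory_rating,model1_rating,model2_rating,model3_rating
AO2,dry,dry,semi-dry,semi-dry,semi-dry
BC1,dry,dry,semi-dry,semi-dry,semi-dry
BB2,sweet,semi-sweet,semi-sweet,semi-sweet,semi-sweet
BB4,semi-sweet,semi-sweet,semi-dry,semi-dry,semi-sweet
BK1,semi-sweet,semi-dry,semi-sweet,semi-dry,semi-dry
LO1,dry,semi-dry,dry,dry,dry
LO3,sweet,semi-sweet,semi-dry,semi-sweet,semi-sweet
NP2,semi-sweet,semi-sweet,semi-dry,semi-dry,semi-sweet
OH2,semi-sweet,semi-sweet,semi-dry,semi-dry,semi-dry
PC1,semi-sweet,semi-dry,semi-sweet,semi-sweet,semi-sweet
WE1,semi-sweet,semi-dry,semi-dry,semi-dry,semi-dry
WE3,semi-sweet,semi-sweet,semi-sweet,semi-dry,semi-sweet
KS2,sweet,semi-sweet,sweet,sweet,sweet
EC2,semi-dry,semi-dry,semi-dry,semi-dry,semi-dry
BD2,semi-dry,semi-dry,semi-dry,semi-dry,semi-dry
BD4,dry,dry,semidry,dry,dry
BD6,semi-dry,semi-dry,semi-dry,semi-dry,semi-dry
BD8,dry,dry,dry,dry,dry
MD2,sweet,semi-sweet,semi-sweet,semi-sweet,semi-sweet
BD9,dry,dry,semi-dry,semi-dry,semidry
BD12,dry,semi-dry,semi-dry,semi-dry,semi-dry
BD14,sweet,semi-dry,semi-dry,semi-dry,semi-dry
WW2,dry,semi-dry,semi-dry,semi-dry,semi-dry
WW4,semi-sweet,semi-dry,semi-dry,semi-dry,semi-dry
EC3,dry,dry,semi-dry,semi-dry,semi-dry
SH1,dry,semi-dry,semi-dry,semi-dry,semi-dry
SH5,sweet,semi-dry,dry,semi-dry,semi-dry
SH7,dry,dry,semi-dry,semi-dry,semi-dry
SH11,sweet,dry,sweet,dry,dry
SH13,semi-sweet,semi-dry,semi-dry,semi-dry,semi-dry
TC2,dry,dry,semi-dry,semi-dry,semi-dry
PF2,dry,dry,semi-dry,semi-dry,semi-dry
KS4,semi-dry,semi-dry,semi-dry,semi-dry,semi-dry
KS7,semi-dry,semi-dry,semi-dry,semi-dry,semi-sweet
TC3,sweet,semi-dry,semi-dry,semi-dry,semi-dry
RB1,dry,semi-dry,semi-dry,semi-dry,semi-dry
RB3,dry,semi-dry,semi-dry,semi-dry,semi-dry
LA1,dry,semi-dry,semi-dry,semi-dry,semi-dry
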