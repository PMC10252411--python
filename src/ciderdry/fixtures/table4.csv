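set,sample_id,irf_score,irf_rating_no_ph,irf_rating_ph,nyca_score,nyca_rating,sensory_score,sensory_rating
calibration,AO1,10.049,sweet,sweet,10.050,sweet,5.5,semi-sweet
calibration,AW1,9.259,sweet,sweet,8.510,sweet,4.5,semi-sweet
calibration,BB1,3.814,semi-sweet,sweet,3.060,semi-sweet,3.4,semi-sweet
calibration,BB3,9.534,sweet,sweet,8.780,sweet,5.6,semi-sweet
calibration,BH1,3.979,semi-sweet,sweet,3.980,semi-sweet,4.8,semi-sweet
calibration,BK2,1.213,semi-dry,semi-sweet,1.210,semi-dry,2.9,semi-dry
calibration,LO2,2.587,semi-sweet,sweet,1.837,semi-dry,1.2,dry
calibration,NP1,0.020,dry,semi-sweet,0.020,dry,2.3,semi-dry
calibration,OH1,0.034,dry,semi-sweet,0.100,dry,1.6,dry
calibration,SH1,0.009,dry,semi-sweet,0.002,dry,1.9,dry
calibration,WC1,0.002,dry,semi-sweet,0.002,dry,1.4,dry
calibration,WE2,3.211,semi-sweet,semi-dry,3.211,semi-sweet,5.1,semi-sweet
calibration,KS1,7.265,sweet,sweet,7.260,sweet,5.2,semi-sweet
calibration,EC1,0.920,dry,semi-sweet,0.920,dry,2.1,semi-dry
calibration,BD1,0.020,dry,semi-dry,0.020,dry,2.3,semi-dry
calibration,BD3,0.460,dry,semi-sweet,0.460,dry,2.0,dry
calibration,BD5,4.330,sweet,sweet,4.330,sweet,3.6,semi-dry
calibration,BD7,2.640,semi-sweet,semi-sweet,2.640,semi-sweet,3.1,semi-dry
calibration,MD1,4.069,sweet,sweet,3.320,semi-sweet,3.6,semi-dry
calibration,MD3,1.008,semi-dry,semi-sweet,0.258,dry,2.9,semi-dry
calibration,BD11,4.772,sweet,sweet,4.522,sweet,3.5,semi-dry
calibration,BD13,0.048,dry,semi-dry,0.047,dry,1.8,dry
calibration,WW1,11.000,sweet,sweet,11.000,sweet,2.6,semi-dry
calibration,WW3,1.000,dry,semi-sweet,1.000,dry,3.0,semi-dry
calibration,WW5,5.000,sweet,sweet,4.740,sweet,2.9,semi-dry
calibration,EC4,4.137,sweet,sweet,3.640,semi-sweet,3.0,semi-dry
calibration,SH3,9.000,sweet,semi-sweet,8.250,sweet,2.0,dry
calibration,SH6,0.622,dry,semi-dry,0.122,dry,2.2,semi-dry
calibration,SH8,0.521,dry,semi-dry,0.521,dry,2.6,semi-dry
calibration,SH12,1.657,semi-dry,semi-sweet,1.450,semi-dry,3.4,semi-dry
calibration,TC1,0.533,dry,semi-dry,0.533,dry,2.3,semi-dry
calibration,PF1,7.333,sweet,sweet,7.333,sweet,1.8,dry
calibration,KS3,0.022,dry,semi-dry,0.001,dry,2.5,semi-dry
calibration,KS5,0.622,dry,semi-dry,0.622,dry,2.8,semi-dry
calibration,KS8,20.449,sweet,sweet,20.450,sweet,6.3,sweet
calibration,TC4,0.037,dry,semi-dry,0.012,dry,2.8,semi-dry
calibration,RB2,0.140,dry,semi-sweet,0.140,dry,2.2,semi-dry
calibration,WW6,1.000,dry,semi-sweet,1.000,dry,2.3,semi-dry
validation,AO2,0.002,dry,semi-sweet,0.002,dry,2.0,dry
validation,BC1,0.002,dry,semi-sweet,0.002,dry,1.5,dry
validation,BB2,6.700,sweet,sweet,5.950,sweet,5.2,semi-sweet
validation,BB4,3.744,semi-sweet,sweet,2.990,semi-sweet,4.4,semi-sweet
validation,BK1,3.994,semi-sweet,sweet,3.994,semi-sweet,3.5,semi-dry
validation,LO1,1.335,semi-dry,semi-sweet,0.580,dry,2.3,semi-dry
validation,LO3,5.827,sweet,sweet,5.080,sweet,4.4,semi-sweet
validation,NP2,3.722,semi-sweet,sweet,2.970,semi-sweet,4.3,semi-sweet
validation,OH2,4.617,sweet,sweet,3.870,semi-sweet,4.1,semi-sweet
validation,PC1,3.934,semi-sweet,sweet,3.934,semi-sweet,3.8,semi-dry
validation,WE1,3.080,semi-sweet,sweet,3.080,semi-sweet,3.9,semi-dry
validation,WE3,3.353,semi-sweet,sweet,3.353,semi-sweet,4.4,semi-sweet
validation,KS2,11.789,sweet,sweet,11.789,sweet,7.0,semi-sweet
validation,EC2,1.850,semi-dry,semi-sweet,1.850,semi-dry,2.3,semi-dry
validation,BD2,2.195,semi-dry,semi-sweet,2.195,semi-dry,2.2,semi-dry
validation,BD4,0.004,dry,semi-dry,0.004,dry,1.8,dry
validation,BD6,1.670,semi-dry,semi-sweet,1.670,semi-dry,3.8,semi-dry
validation,BD8,0.019,dry,semi-sweet,0.019,dry,1.7,dry
validation,MD2,8.261,sweet,sweet,7.510,sweet,5.8,semi-sweet
validation,BD9,0.032,dry,semi-sweet,0.032,dry,1.8,dry
validation,BD12,0.051,dry,semi-sweet,0.051,dry,2.4,semi-dry
validation,BD14,4.949,sweet,sweet,4.949,sweet,3.2,semi-dry
validation,WW2,1.000,dry,semi-sweet,1.000,dry,2.6,semi-dry
validation,WW4,4.000,semi-sweet,sweet,4.000,semi-sweet,2.6,semi-dry
validation,EC3,0.030,dry,semi-sweet,0.030,dry,2.0,dry
validation,SH1,0.766,dry,semi-sweet,0.766,dry,3.7,semi-dry
validation,SH5,178.000,sweet,sweet,178.000,sweet,2.7,semi-dry
validation,SH7,0.011,dry,semi-sweet,0.011,dry,1.9,dry
validation,SH11,9.554,sweet,sweet,9.554,sweet,1.8,dry
validation,SH13,3.299,semi-sweet,sweet,3.299,semi-sweet,3.3,semi-dry
validation,TC2,0.047,dry,semi-sweet,0.047,dry,2.0,dry
validation,PF2,0.019,dry,semi-sweet,0.019,dry,2.0,dry
validation,KS4,1.660,semi-dry,semi-sweet,1.660,semi-dry,3.7,semi-dry
validation,KS7,1.724,semi-dry,semi-dry,1.724,semi-dry,2.9,semi-dry
validation,TC3,11.931,sweet,sweet,11.931,sweet,3.1,semi-dry
validation,RB1,0.179,dry,semi-dry,0.179,dry,2.4,semi-dry
validation,RB3,0.193,dry,semi-sweet,0.193,dry,2.1,semi-dry
validation,LA1,0.011,dry,semi-sweet,0.011,dry,3.1,semi-dry
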