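set,statistic,alcohol,ph,malic_acid,titratable_acidity,residual_sugar,polyphenols,hydroxybenzoic,hydroxycinnamic,abs320,abs280
calibration,max,20.22,3.98,0.83,0.93,7689.00,5399.0,109.7,398.0,0.3758,4.5855
calibration,min,5.03,3.26,0.00,0.25,1.00,50.4,15.0,7.0,0.0120,0.0279
calibration,median,7.28,3.62,0.47,0.56,361.83,435.7,24.5,76.5,0.0760,0.2329
calibration,q1,6.69,3.50,0.22,0.43,8.08,210.5,20.8,27.0,0.0523,0.1207
calibration,q3,8.16,3.82,0.61,0.69,1738.67,702.1,28.8,139.3,0.1492,0.3858
calibration,average,7.73,3.64,0.40,0.56,1248.51,824.1,28.9,101.2,0.1117,0.5940
validation,max,19.03,3.99,1.45,1.62,17059.00,5356.2,94.3,390.3,0.4266,3.2950
validation,min,5.67,3.27,0.00,0.33,1.00,62.0,16.0,15.0,0.0248,0.0476
validation,median,7.68,3.63,0.48,0.55,691.17,409.4,24.0,75.7,0.0812,0.2130
validation,q1,6.79,3.54,0.37,0.48,11.67,258.0,20.0,30.3,0.0558,0.1028
validation,q3,8.18,3.68,0.61,0.69,1953.25,744.4,31.3,126.3,0.1730,0.3730
validation,average,7.98,3.61,0.50,0.61,1758.83,793.8,31.4,101.5,0.1313,0.4811
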