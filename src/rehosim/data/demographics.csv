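study,total,female,male,age_mean,age_sd
AnnArbor_b,35,19,16,47.6,26.3
Atlanta,28,15,13,30.9,9.9
Baltimore,23,15,8,29.3,5.5
Bangor,20,0,20,23.4,5.3
Beijing_Zang,192,118,74,21.2,1.8
Berlin_Margulies,26,13,13,29.8,5.2
Cambridge_Buckner,198,123,75,21.0,2.3
Cleveland,31,20,11,43.5,11.1
COBRE,74,23,51,35.8,11.6
Dallas,24,12,12,42.6,20.1
ICBM,86,45,41,44.2,17.9
Leiden_2180,12,0,12,23.0,2.5
Leiden_2200,19,8,11,21.7,2.6
Leipzig,37,21,16,26.2,5.0
Milwaukee_b,46,31,15,53.6,5.8
Munchen,16,6,10,68.4,4.0
Newark,19,10,9,24.1,3.9
NewHaven_a,19,9,10,31.0,10.3
NewHaven_b,16,8,8,26.9,6.3
NewYork_b,20,12,8,29.8,9.9
Orangeburg,20,5,15,40.6,11.0
Oulu,103,66,37,21.5,0.6
Oxford,22,10,12,29.0,3.8
PaloAlto,17,15,2,32.5,8.1
Pittsburgh,17,7,10,37.9,9.0
Queensland,19,8,11,25.9,3.9
SaintLouis,31,17,14,25.1,2.3
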