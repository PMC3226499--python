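chemical,group,vbs,VEGFR1,VEGFR2,VEGFR3,TIE2,EphB2,PI3Ka,PTEN
Abamectin,pvdc,5.19,,,,38.8,17,6.4,
Maneb,pvdc,4.69,4.1,31,12,8.08,23,,0.9
Metiram-zinc,pvdc,4.35,6.6,41,22,15,,29,12
Oxytetracycline dihydrate,pvdc,3.85,,19,6.5,15,,6.2,1.6
Perfluorooctanesulfonic acid,pvdc,3.48,8.2,50,8,4.43,,6.5,17
Perfluorooctanoic acid,pvdc,3.04,,,,31.9,,,
Mancozeb,pvdc,3.00,19,5.9,1.3,10.4,21,20,0.23
Emamectin benzoate,pvdc,2.91,,,,,21,7.9,2.1
"2,2-bis-(p-Hydroxyphenyl)-1,1,1-trichloroethane",pvdc,2.28,,,,,,28,
Diclosulam,pvdc,2.09,,,,,,,50
Milbemectin,pvdc,1.49,,,,,20,11,12
Captan,non_pvdc,1.14,,,,,,,35
Cyclanilide,non_pvdc,0.21,,,,,50,,3.9
Sethoxydim,non_pvdc,0.00,,,,,,,22
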