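chemical,species,category,lel,vbs
Diniconazole,rat,general fetal pathology; embryo fetal loss; maternal pregnancy loss; skeletal: appendicular; skeletal: axial; urogenital: renal,,4.57
Naled,rat,embryo fetal loss; trunk: body wall,,4.22
"(Z,E)-Fenpyroximate",rat,skeletal: axial,,3.88
Cyazofamid,rat,skeletal: axial,,3.34
Chlorothalonil,rat,embryo fetal loss; maternal pregnancy loss,,3.28
Lactofen,rat,fetal weight reduction; maternal pregnancy loss; skeletal: appendicular; skeletal: axial,,3.18
Spirodiclofen,rat,urogenital: renal,,3.15
Thiodicarb,rat,fetal weight reduction; general fetal pathology; embryo fetal loss; maternal pregnancy loss; skeletal: axial,,2.97
Alachlor,rat,fetal weight reduction; embryo fetal loss,,2.97
Emamectin benzoate,rat,fetal weight reduction; skeletal: appendicular; skeletal: axial; skeletal: cranial,,2.91
Fluoxastrobin,rat,skeletal: appendicular,,2.79
Hexythiazox,rat,skeletal: appendicular,,2.78
Tetraconazole,rat,general fetal pathology; skeletal: axial; urogenital: renal; urogenital: ureteric,,2.23
Prodiamine,rat,neurosensory: eye,,2.19
Fenpropathrin,rat,maternal pregnancy loss,,2.18
Acetochlor,rat,fetal weight reduction; general fetal pathology; embryo fetal loss; maternal pregnancy loss; skeletal: axial,,2.16
Prallethrin,rat,maternal pregnancy loss,,2.11
Thiazopyr,rat,skeletal: axial,,2.00
Fludioxonil,rat,urogenital: renal; urogenital: ureteric,,1.82
Profenofos,rat,maternal pregnancy loss,,1.71
Metolachlor,rat,fetal weight reduction; embryo fetal loss; maternal pregnancy loss,,1.57
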