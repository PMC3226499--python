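chemical,species,category,lel,vbs
Methylene bis(thiocyanate),rabbit,maternal pregnancy loss,,6.55
Trifloxystrobin,rabbit,skeletal: axial,,4.26
Propargite,rabbit,skeletal: axial,,3.79
Etoxazole,rabbit,skeletal: axial,,3.66
Fenoxycarb,rabbit,skeletal: axial,,3.60
Azamethiphos,rabbit,maternal pregnancy loss,,3.10
Quinoxyfen,rabbit,maternal pregnancy loss,,3.02
Butafenacil,rabbit,embryo fetal loss,,2.94
Dazomet,rabbit,general fetal pathology; embryo fetal loss; skeletal: axial,,2.61
Rimsulfuron,rabbit,embryo fetal loss; maternal pregnancy loss,,2.52
Dichlorvos,rabbit,maternal pregnancy loss,,2.34
Bensulide,rabbit,maternal pregnancy loss,,2.17
Flumiclorac-pentyl,rabbit,maternal pregnancy loss,,2.11
Diclosulam,rabbit,maternal pregnancy loss,,2.09
Propetamphos,rabbit,embryo fetal loss,,2.08
Butachlor,rabbit,fetal weight reduction; embryo fetal loss; maternal pregnancy loss,,1.99
Dicofol,rabbit,maternal pregnancy loss,,1.92
Oxyfluorfen,rabbit,embryo fetal loss; maternal pregnancy loss,,1.82
Famoxadone,rabbit,embryo fetal loss; maternal pregnancy loss,,1.82
Flufenpyr-ethyl,rabbit,maternal pregnancy loss,,1.73
Dicrotophos,rabbit,fetal weight reduction; maternal pregnancy loss,,1.59
Carboxin,rabbit,maternal pregnancy loss,,1.56
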