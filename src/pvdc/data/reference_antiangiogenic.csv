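chemical,vbs,CCL2_down,CXCL10_up,uPAR_updown,PAI1_updown,VEGFR2_down,TIE2_inhib
5HPP-33,6.61,0.625,,1.25,20,20,
Thalidomide,1.76,0.625,,2.5,40,,
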