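name,category,cmax_nM,dose1_nM,dose2_nM,dose3_nM,dose4_nM
Dofetilide,high,2.14,0.3,1,3,10
Bepridil,high,31.5,35,105,210,315
Quinidine,high,843,100,300,900,2700
Terfenadine,intermediate,0.286,0.08,0.8,8,80
Chloroquine,intermediate,250,250,750,2500,25000
Chlorpromazine,intermediate,34.5,35,350,1050,3500
Cisapride,intermediate,2.58,2.5,7.5,25,125
Diltiazem,low,128,3,10,30,90
Mexiletine,low,2500,625,1250,2500,3750
Ranolazine,low,1948,1000,2300,6900,15000
Verapamil,low,45,1,10,50,150
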