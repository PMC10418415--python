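compound,ec50_p80_nM,emax_p80,hill_p80,ec50_amp_nM,emax_amp,hill_amp,ead_onset_nM,ead_probability_at_top,cessation_nM,irregularity_gain
Dofetilide,2,1.5,1.5,2,0,1,2,0.9,,0
Bepridil,250,0.8,1.5,250,0,1,200,0.6,,0
Quinidine,500,1.4,1.5,500,0,1,400,0.9,,0
Terfenadine,20,0.9,1.2,20,0,1,100,0.8,,0
Chloroquine,6000,1.0,1.2,6000,0,1,30000,0.8,,0
Chlorpromazine,1200,0.9,1.2,1200,0,1,4000,0.8,,0
Cisapride,40,0.9,1.2,40,0,1,150,0.8,,0
Diltiazem,30,0.05,1,30,0.3,1,,0,,0.35
Mexiletine,2000,0.05,1,2000,0.4,1,,0,,0
Ranolazine,5000,0.15,1,5000,0.2,1,,0,,0
Verapamil,40,0.03,1,40,0.5,1,,0,,0
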