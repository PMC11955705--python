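compound,invitro_ic50_uM,invitro_ratio,insilico_median_ic50_uM,insilico_bayes_mean_uM,insilico_bayes_sd_uM
Bepridil,0.7,22,0.77,0.84,0.06
Chlorpromazine,1.02,28,2.5,2.9,0.13
Clarithromycin,16,13,3336,2795,251
Clozapine,1.5,21,1.5,1.6,0.07
Diltiazem,1,8,0.28,0.3,0.0077
Disopyramide,9.3,13,407,468,27
Domperidone,0.2,10,5,11,2.4
Droperidol,0.18,11,1.5,1.8,0.12
Flecainide,1.1,2,7.9,10,1.7
Ibutilide,2,20,16,27.8,10
Loratadine,0.017,35,5.6,5.7,0.34
Mexiletine,0.9,0.4,8.7,9.9,1.1
Mibefradil,0.18,13,0.28,0.30,0.01
Nifedipine,0.04,5,0.0038,0.0041,0.0001
Nitrendipine,0.06,18,0.0054,0.006,0.0003
Ondansetron,14,34,7.4,8.02,0.24
Procainamide,2215,38,138,157,12
Quinidine,3.6,1,2.06,2.3,0.15
Ranolazine,17,9,61,62,12
Terodiline,0.7,5,2.4,2.5,0.11
Vandetanib,2.7,9,5.2,6.3,0.35
Verapamil,0.04,2,0.08,0.08,0.002
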