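name,abbreviation,mw,log_kow,cv_ug_per_ml,solvent
Kojic acid,KA,142.11,-0.9,1.04e4,Water
Caffeine,CAF,194.19,-0.1,1.00e4,Water
Isosorbide 5-mononitrate,ISMN,191.13,-0.2,1.10e4,Water
Lidocaine,LID (pH 5.0),234.34,-0.9,9.56e3,pH 5.0 citrate buffer
Sodium benzoate,BA (pH 3.0),122.12,1.9,1.83e3,pH 3.0 citrate buffer
Sodium benzoate,BA (pH 7.0),121.12,-2.3,1.08e4,pH 7.0 PBS
Methyl paraben,MP,152.15,2.0,1.39e3,Water
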