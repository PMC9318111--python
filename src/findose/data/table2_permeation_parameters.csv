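abbreviation,membrane,kp_cm_per_h,kp_se_cm_per_h,k,k_se
KA,porcine_skin,1.30e-3,0.37e-3,1.08e-1,0.15e-1
CAF,porcine_skin,2.32e-3,0.12e-3,1.36e-1,0.62e-1
ISMN,porcine_skin,1.15e-3,0.32e-3,1.01e-1,0.26e-1
LID (pH 5.0),porcine_skin,1.44e-3,0.69e-3,1.25e-1,0.83e-1
BA (pH 3.0),porcine_skin,2.27e-2,0.07e-2,1.51,0.09
BA (pH 7.0),porcine_skin,2.11e-3,2.10e-3,1.44e-1,1.31e-1
MP,porcine_skin,1.06e-2,0.15e-2,7.08e-1,2.90e-1
KA,strat_m,1.46e-4,0.30e-4,5.77e-2,2.32e-2
CAF,strat_m,1.23e-3,0.26e-3,4.22e-1,0.91e-1
ISMN,strat_m,1.49e-3,0.48e-3,1.04,0.37
LID (pH 5.0),strat_m,4.72e-5,2.43e-5,2.15e-2,1.71e-2
BA (pH 3.0),strat_m,1.01e-2,0.03e-2,1.57,0.20
BA (pH 7.0),strat_m,2.51e-5,0.25e-5,6.73e-3,1.04e-3
MP,strat_m,5.20e-3,1.08e-3,3.08,0.65
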