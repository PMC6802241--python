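block,ed,sex,lower,upper,calibrated_mean,ui_lo,ui_hi,unit
naive_incidence,AN,M,,,,,,age_specific
naive_incidence,AN,F,,,,,,age_specific
naive_incidence,BED,M,,,,,,age_specific
naive_incidence,BED,F,,,,,,age_specific
naive_incidence,BN,M,,,,,,age_specific
naive_incidence,BN,F,,,,,,age_specific
naive_incidence,OSFED,M,,,,,,age_specific
naive_incidence,OSFED,F,,,,,,age_specific
relapse_p_first,AN,M,5,40,21.3,2.9,52.7,percent
relapse_p_first,AN,F,5,40,20.4,2.3,55.6,percent
relapse_p_first,BED,M,5,40,9.8,0.7,28.2,percent
relapse_p_first,BED,F,5,40,25.2,3.6,52.0,percent
relapse_p_first,BN,M,5,40,25.0,2.2,56.9,percent
relapse_p_first,BN,F,5,40,17.7,1.4,47.0,percent
relapse_p_first,OSFED,M,5,40,12.2,0.1,50.6,percent
relapse_p_first,OSFED,F,5,40,13.1,0.1,52.1,percent
relapse_decay,AN,M,0,1,0.52,0.07,0.94,unitless
relapse_decay,AN,F,0,1,0.52,0.05,0.94,unitless
relapse_decay,BED,M,0,1,0.43,0.01,0.95,unitless
relapse_decay,BED,F,0,1,0.57,0.07,0.95,unitless
relapse_decay,BN,M,0,1,0.49,0.03,0.97,unitless
relapse_decay,BN,F,0,1,0.49,0.03,0.89,unitless
relapse_decay,OSFED,M,0,1,0.49,0.02,0.93,unitless
relapse_decay,OSFED,F,0,1,0.42,0.05,0.90,unitless
remission,AN,M,0,10,7.8,0.2,20.1,percent
remission,AN,F,0,10,8.5,0.9,20.3,percent
remission,BED,M,0,10,16.3,6.4,27.3,percent
remission,BED,F,0,10,7.0,0.3,21.5,percent
remission,BN,M,0,10,8.5,1.4,18.9,percent
remission,BN,F,0,10,10.0,2.1,21.7,percent
remission,OSFED,M,0,10,10.9,1.6,24.6,percent
remission,OSFED,F,0,10,13.6,3.6,27.2,percent
coverage,AN,M,0,50,28.2,2.4,49.0,percent
coverage,AN,F,0,30,14.0,1.9,28.9,percent
coverage,BED,M,0,51,30.1,4.8,50.2,percent
coverage,BED,F,10,53,29.7,11.0,52.2,percent
coverage,BN,M,0,30,15.7,1.3,28.5,percent
coverage,BN,F,0,37,17.7,1.9,35.8,percent
coverage,OSFED,M,0,30,16.5,2.1,28.5,percent
coverage,OSFED,F,0,30,16.7,1.4,28.8,percent
efficacy,AN,M,1.5,10,7.59,1.32,19.83,ratio
efficacy,AN,F,1.5,10,8.00,1.73,18.73,ratio
efficacy,BED,M,1.2,2.0,2.08,1.36,3.37,ratio
efficacy,BED,F,1.2,2.0,1.81,1.10,2.86,ratio
efficacy,BN,M,1.2,2.0,1.75,1.07,2.92,ratio
efficacy,BN,F,1.2,2.0,1.74,1.10,3.13,ratio
efficacy,OSFED,M,1.2,2.0,1.80,1.07,3.01,ratio
efficacy,OSFED,F,1.2,2.0,1.83,1.05,3.01,ratio
crossover,AN>BED,M,0,1.5,1.2,0.1,3.0,percent
crossover,AN>BED,F,0,1.5,1.2,0.1,3.1,percent
crossover,AN>BN,M,0,0.03,0.0,0.0,0.1,percent
crossover,AN>BN,F,0,0.4,0.3,0.0,0.9,percent
crossover,AN>OSFED,M,0,4.5,4.0,0.2,10.3,percent
crossover,AN>OSFED,F,0,4.5,3.8,0.4,10.4,percent
crossover,BED>AN,M,0,1.3,1.1,0.2,2.9,percent
crossover,BED>AN,F,0,1.2,0.5,0.0,1.6,percent
crossover,BED>BN,M,0,0.2,0.2,0.0,0.4,percent
crossover,BED>BN,F,0,0.4,0.3,0.0,0.9,percent
crossover,BED>OSFED,M,0,4.9,5.4,0.2,12.1,percent
crossover,BED>OSFED,F,0,4.7,3.4,0.2,8.2,percent
crossover,BN>AN,M,0,0.9,0.7,0.1,1.9,percent
crossover,BN>AN,F,0,2.1,1.3,0.1,3.4,percent
crossover,BN>BED,M,0,1.7,1.4,0.1,3.7,percent
crossover,BN>BED,F,0,1.7,1.4,0.1,3.1,percent
crossover,BN>OSFED,M,0,5.2,4.5,0.5,9.9,percent
crossover,BN>OSFED,F,0,5.0,4.5,0.4,10.1,percent
crossover,OSFED>AN,M,0,4.0,0.4,0.0,1.6,percent
crossover,OSFED>AN,F,0,3.6,0.1,0.0,0.6,percent
crossover,OSFED>BED,M,0,1.6,0.6,0.1,1.6,percent
crossover,OSFED>BED,F,0,1.6,0.7,0.0,2.2,percent
crossover,OSFED>BN,M,0,0.6,0.1,0.0,0.4,percent
crossover,OSFED>BN,F,0,1.3,0.4,0.0,1.2,percent
smr,AN,M,4.17,8.26,6.71,1.43,13.12,ratio
smr,AN,F,4.17,8.26,6.31,1.33,12.44,ratio
smr,BED,M,1.46,2.52,2.01,1.08,3.53,ratio
smr,BED,F,1.46,2.52,2.15,1.10,3.68,ratio
smr,BN,M,1.44,2.59,2.26,1.19,3.49,ratio
smr,BN,F,1.44,2.59,2.31,1.09,3.64,ratio
smr,OSFED,M,1.46,2.52,2.17,1.15,3.81,ratio
smr,OSFED,F,1.46,2.52,2.07,1.12,3.67,ratio
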