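label,units,mean_wt,sem_wt,n_wt,mean_het,sem_het,n_het,printed_t,printed_df
soma_area,um^2,257.7,16.2,39,216.2,11.19,33,2.031,70
neurite_outgrowth,um,848.1,62.41,39,452.2,46.27,33,4.94,70
synaptic_puncta_density,puncta/50um,11.16,0.4508,55,7.569,0.2818,51,6.643,104
social_approach,time ratio,1.457,0.060,20,1.575,0.175,20,0.6379,38
social_novelty,time ratio,1.573,0.130,20,1.021,0.078,20,3.643,38
social_preference,time ratio,1.599,0.149,20,1.187,0.108,20,2.24,38
brain_volume,mm^3,409.7,5.29,12,417.5,4.16,11,1.156,21
relative_cortex_volume,percent,29.81,0.16,12,30.09,0.13,11,1.35,21
relative_amygdala_volume,percent,8.331,0.145,12,8.693,0.082,11,2.109,21
relative_hippocampus_volume,percent,4.842,0.042,12,4.885,0.0288,11,0.8351,21
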