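# units: kidney_weight_at_unx=g terminal_kidney_weight=g uev_excretion_baseline=1e12_uEVs/day uev_excretion_sacrifice=1e12_uEVs/day
group,kidney_weight_at_unx,terminal_kidney_weight,uev_excretion_baseline,uev_excretion_sacrifice
UNX,1.2,1.7,0.66,0.50
5/6NX,1.2,1.6,0.81,0.56
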