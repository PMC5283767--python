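# Idealised single-insecticide deployment with a relaxed-selection
# interruption: insecticide 1 is deployed for generations 1-3, withdrawn
# for generations 4-12, then redeployed.
[locus1]
effectiveness = 1.0
dominance = 1.0
rr_restoration = 1.0
cost = 0.0
cost_dominance = 0.0

[locus2]
effectiveness = 1.0
dominance = 1.0
rr_restoration = 1.0
cost = 0.0
cost_dominance = 0.0

[exposure]
exposure = 0.9
male_exposure_prop = 1.0
correct_mix_deploy = 1.0

[simulation]
strategy = single
insecticide = 1
start_freq_1 = 0.001
start_freq_2 = 0.0
recombination = 0.5
threshold = 0.5
max_generations = 20
relax_generations = 4-12
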