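# Idealised two-insecticide scenario: both insecticides kill every SS
# mosquito they contact, resistance is fully dominant and fully restores
# fitness, and carries no cost; 90% of both sexes are exposed.
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

[interaction]
lambda_ab = 1.0
lambda_Ab = 1.0
lambda_aB = 1.0
lambda_AB = 1.0

[simulation]
strategy = mixture
start_freq_1 = 0.01
start_freq_2 = 0.001
recombination = 0.5
threshold = 0.5
max_generations = 500
insecticide_order = 1,2
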