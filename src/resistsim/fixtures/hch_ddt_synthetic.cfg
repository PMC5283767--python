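# SYNTHETIC, INCOMPLETE stand-in for a DDT/HCH-style field calibration.
# Locus 1 uses the published DDT survival figures (SS fitness 0.27 after
# exposure, RR fitness 0.50, i.e. effectiveness 0.73, selection 0.23);
# the dominance value and the entire locus-2 (HCH-like) calibration are
# placeholders that users must replace with their own estimates.
[locus1]
effectiveness = 0.73
dominance = 0.5
selection = 0.23
cost = 0.0
cost_dominance = 0.0

[locus2]
effectiveness = 0.73
dominance = 0.5
selection = 0.23
cost = 0.0
cost_dominance = 0.0

[exposure]
exposure = 0.9
male_exposure_prop = 1.0
correct_mix_deploy = 1.0

[simulation]
strategy = mixture
start_freq_1 = 0.1
start_freq_2 = 0.01
recombination = 0.5
threshold = 0.5
max_generations = 2000
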