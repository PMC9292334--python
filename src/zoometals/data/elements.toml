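# Default per-element stoichiometric constants.
# Quotas are absolute mol metal : mol C ratios; k_uptake in mol m^-3.

[Fe]
q_max_nano = 80e-6
q_max_diatom = 80e-6
q_zoo = 10e-6
k_uptake = 0.1e-6
ae_max = 0.8
ae_shape = 1.0

[Zn]
q_max_nano = 40e-6
q_max_diatom = 123e-6
q_zoo = 10e-6
k_uptake = 1.0e-6
ae_max = 0.8
ae_shape = 1.0

[Cu]
q_max_nano = 16e-6
q_max_diatom = 16e-6
q_zoo = 10e-6
k_uptake = 0.5e-6
ae_max = 0.8
ae_shape = 1.0

[Co]
q_max_nano = 1.2e-6
q_max_diatom = 1.2e-6
q_zoo = 0.16e-6
k_uptake = 0.02e-6
ae_max = 0.8
ae_shape = 1.0

[Mn]
q_max_nano = 8e-6
q_max_diatom = 8e-6
q_zoo = 1e-6
k_uptake = 0.1e-6
ae_max = 0.8
ae_shape = 1.0
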