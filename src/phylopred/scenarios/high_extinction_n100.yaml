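name: high_extinction_n100
mode: taxa
n_extant: 100
spec_rate: 1.0
ext_rate: 0.9
speciation_mode: asymmetric
r: [0.25, 0.5, 0.75]
reps: 1000
missing_scheme: {kind: extinct_only}
n_taxa: 100
transform: none
standardize: total_length
seed: 0
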