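# deterministic ladder tree (extreme-extinction end member)
name: pectinate_end_member
mode: taxa
n_extant: 100
spec_rate: 0.5
ext_rate: 1.0
speciation_mode: asymmetric
fixed_tree: pectinate
r: [0.25, 0.5, 0.75]
reps: 1000
missing_scheme: {kind: random_fraction, param: 0.10}
n_taxa: null
transform: none
standardize: total_length
seed: 0
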