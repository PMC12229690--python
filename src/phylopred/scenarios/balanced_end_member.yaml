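# deterministic fully balanced 128-tip tree; replicates vary traits only
name: balanced_end_member
mode: taxa
n_extant: 128
spec_rate: 0.4
ext_rate: 0.5
speciation_mode: symmetric
fixed_tree: balanced
r: [0.25, 0.5, 0.75]
reps: 1000
missing_scheme: {kind: random_fraction, param: 0.10}
n_taxa: null
transform: none
standardize: total_length
seed: 0
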