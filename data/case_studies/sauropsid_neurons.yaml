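tree_file: sauropsid_neurons.nwk
traits_file: sauropsid_neurons.csv
formula: "neurons ~ brain_mass * C(group, Treatment('avian'))"
log10_columns: [neurons, brain_mass]
targets: [Tyrannosaurus_rex]
grafts: []
transform: none
parameters: {ev_frac: 0.31}
derived: {brain_mass: "ev_frac * endocranial_volume"}
loo: false
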