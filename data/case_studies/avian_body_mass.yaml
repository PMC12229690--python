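tree_file: avian_body_mass.nwk
traits_file: avian_body_mass.csv
formula: body_mass ~ humerus_length
log10_columns: [body_mass, humerus_length]
targets: missing
# one entry per fossil: {label, anchor (tip or clade list), divergence_age, tip_age}
grafts: []
transform: none
loo: false
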