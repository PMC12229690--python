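tree_file: primate_neonatal_brain.nwk
traits_file: primate_neonatal_brain.csv
formula: neonatal_brain ~ adult_brain
log10_columns: [neonatal_brain, adult_brain]
targets: missing
grafts: []
transform: none
loo: true
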