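tree_file: cricket_carrier_frequency.nwk
traits_file: cricket_carrier_frequency.csv
formula: carrier_frequency ~ file_length
log10_columns: [carrier_frequency, file_length]
targets: missing
grafts: []
transform: kappa0
loo: false
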