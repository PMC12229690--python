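# Case-study configurations

These YAML files encode the four published case-study analyses (model
formulas, transforms, grafting and validation settings). The trait tables
and trees themselves are third-party supplementary material and are not
redistributed; to run an analysis, place the files referenced by each
config in this directory:

- `primate_neonatal_brain.{csv,nwk}` — 45 extant primates with neonatal and
  adult brain size (log10 g), plus 29 species with adult size only; the
  dated primate tree containing all of them.
- `avian_body_mass.{csv,nwk}` — 247 extant birds with body mass (log10 g)
  and humerus length (log10 mm); the extant time tree. Fossil placements
  (41 taxa) go in the config's `grafts` list with first/last appearance
  ages.
- `cricket_carrier_frequency.{csv,nwk}` — 94 bush-cricket species with
  stridulatory file length and carrier frequency (both log10); the
  parsimony tree without branch lengths (κ = 0 is applied), with 18 taxa
  inserted as polytomies.
- `sauropsid_neurons.{csv,nwk}` — 254 sauropsids with telencephalic neuron
  count and brain mass (log10); time tree plus the T. rex graft. Brain mass
  for the fossil derives from endocranial volume via the `ev_frac`
  parameter (default 0.31).

Run with:  phylopred case-study --config data/case_studies/<name>.yaml --out out/
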