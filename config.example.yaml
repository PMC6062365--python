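# Example configuration for `toxtriad all --config config.example.yaml`.
# Small synthetic profile; remove `synthetic` overrides (and raise
# n_repeats to 20, n_trees to 500) for the full benchmark-shaped protocol.
cohort_dir: cohort
output_dir: results
master_seed: 1
n_repeats: 5
n_folds: 5
n_trees: 300
n_scrambles: 10
scramble_cells: 5
synthetic:
  n_compounds: 200
  n_toxic: 50
  n_chem_descriptors: 48
  n_targets: 60
  n_cell_lines: 6
  n_concentrations: 10
  n_bioactivity_compounds: 400
combos:
  - [chemical]
  - [target]
  - [cytotox]
  - [chemical, target]
  - [chemical, cytotox]
  - [target, cytotox]
  - [chemical, target, cytotox]
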