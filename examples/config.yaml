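# Full-pipeline run configuration for `hqscape run-all --config config.yaml`.
# Transition-rate keys use the YAML-friendly "from->to" form over the class
# codebook 1=forest 2=cropland 3=shrub 4=grassland 5=water 6=impervious
# 7=wasteland.
outdir: scratch/cli_run
seed: 1
years_per_step: 10.0
simulation:
  grid_rows: 96
  grid_cols: 96
  cell_size: 30.0
  n_years: 3
  forest_fraction_target: 0.9
  settlement_centers: [[72, 24]]
  transition_rates:
    "1->2": 0.05   # cropland expansion into adjacent forest
    "2->6": 0.10   # impervious growth on adjacent cropland
    "3->1": 0.03   # shrub recovering to forest
weights_scheme: queen
moran_permutations: 0
opgd_classes: [3, 8]
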