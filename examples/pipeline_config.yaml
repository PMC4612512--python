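# Full pipeline configuration: `halfsib all --config examples/pipeline_config.yaml`
# Omit the `simulation` block and provide `input: {phenotypes: ..., pedigree: ...}`
# to analyse existing CSV tables instead.
seed: 1
out_dir: halfsib_out
alpha: 0.05        # Wald p-value threshold for the minimal fixed-effect model
jackknife: true    # delete-one-sire-family SEs for every genetic parameter

simulation:        # any SimulationConfig field may be overridden here
  n_sires: 72
  n_dams_per_sire: 3
  n_daughters_per_dam: 4
  attrition_prob: 0.10

traits:
  longevity:
    candidates: [lifetime_matings, start_date, body_size]
    test_transform: none
  early_life_matings:
    candidates: [longevity, start_date, body_size]
    test_transform: log1p   # significance tests on log(x+1); parameters untransformed

correlations:
  - [longevity, early_life_matings]
  - [early_life_matings, later_life_matings]
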