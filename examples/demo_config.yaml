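# Demo pipeline configuration: synthetic cohort with 3 planted ecotypes,
# one remodeled subcluster (embedding shift 2.0 in the last group) and
# planted markers. Run with:
#   ecokit run --config examples/demo_config.yaml --out-dir demo/
seed: 7
simulate:
  n_groups: 2
  n_samples_per_group: 15
  n_subclusters: 9
  k_ecotypes: 3
  cells_per_sample: 300
  embed_dim: 10
  shift_magnitude: 2.0
  remodeled_subclusters: [1]
  n_genes: 300
  n_markers_per_subcluster: 8
  marker_log_fold: 3.0
composition:
  level: subcluster
  denominator: all
divergence:
  n_iterations: 30
  subsample_size: 40
  min_cells_per_group: 200
ecotype:
  ranks: [2, 6]
  runs_per_rank: 30
  final_iters: 500
signatures:
  top_k: 50
  p_filter: 0.05
  group_k: 20
  group_p: 1.0e-4
  bins: 24
  controls: 100
meta:
  n_pseudo_datasets: 3
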