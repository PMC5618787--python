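# Full-pipeline configuration driving the bundled synthetic benchmark.
# Run with:  gsecens run --config examples/pipeline_synthetic.yaml
seed: 1
output_dir: gsecens_out
stages: [ops, rmsf, pca, cluster, classify]
synthetic:
  n_frames: 2000
  noise_sigma_nm: 0.05
thresholds:
  # fixed major-axis length edges (nm); delete to use the mixture fit
  length_edges: [7.6, 8.7]
cluster_cutoff_nm: 0.2
cluster_max_frames: 150
pca_components: 10
log_level: INFO
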