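# Full-pipeline configuration: a scaled-down simulated cohort.
# Run with:  omicstack run-all --config examples/config.yaml
outdir: out
seed: 1
simulation:
  n_subjects: 10
  include_postpartum: true
  modalities:
    - {name: proteome, n_features: 40, n_latent: 8, signal_strength: 0.9,
       n_informative_latent: 3, noise_sd: 0.7, missing_rate: 0.01,
       recovery_rate: 0.3}
    - {name: metabolome, n_features: 50, n_latent: 10, signal_strength: 0.7,
       n_informative_latent: 3, noise_sd: 1.0, recovery_rate: 0.8}
    - {name: immunome, n_features: 30, n_latent: 5, signal_strength: 0.8,
       n_informative_latent: 2, noise_sd: 0.8, recovery_rate: 0.1}
grid:
  alphas: [0.1, 0.5, 0.9]
  n_lambdas: 10
  lambda_min_ratio: 0.01
impute:
  n_trees: 50
bootstrap_iterations: 50
n_thresholds: 6
ablation_orders: [most_important]
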