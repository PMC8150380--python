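# Bundled small-scale demo: a twin-species synthetic world sized so the full
# pipeline (simulate -> ... -> landscape) completes in about a minute.
generator:
  n_genes_a: 600
  n_genes_b: 600
  n_shared_features: 40
  n_private_features_per_species: 6
  n_informative: 8
  effect_size: 1.0
  coef_jitter_sd: 0.3
  noise_sd: 0.5
  essential_prevalence: 0.05
  n_chromosomes: 3
  chrom_length_bp: 5000000
  seed: 11
families: [GLM, XGB]
grid_fractions: [0.3, 0.6, 0.9]
grid_repeats: 1
bootstrap_B: 20
bootstrap_families: [XGB]
transfer_model: XGB
selection:
  alpha_grid: [0.2, 0.5, 0.8]
  n_lambdas: 6
  cv_folds: 3
  ensemble_B: 50
seed: 0
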