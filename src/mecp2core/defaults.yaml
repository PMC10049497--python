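# Versioned default generator parameters. These define the synthetic study
# conditions used by the analysis drivers and the acceptance checks.
version: 1
multi_contrast:
  n_genes: 5000
  n_contrasts: 40
  n_core_up: 150
  n_core_down: 120
  concordance: 0.6
  mean_core_lfc: 0.6
  noise_sd: 0.2
  background_sig_rate: 0.03
  n_inverted: 2
  alpha: 0.01
  max_background_frac: 0.05
counts:
  n_genes: 2000
  n_per_group: 20
  de_fraction: 0.15
  lfc_distribution: exponential
  lfc_mean: 0.5
  dispersion_mean: 0.02
  dispersion_asymptote: 0.005
  size_factor_sd: 0.1
consensus:
  alpha: 0.01
  min_contrasts: 4
power:
  sample_sizes: [10, 9, 8, 7, 6, 5, 4, 3]
  n_reps: 20
  fdr_threshold: 0.01
  fc_cutoffs: [1.0, 1.1, 1.2]
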