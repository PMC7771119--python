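# Demo run: three-site synthetic community (default study-like dimensions),
# full pipeline from simulation through the mixed-model stage.
synthetic:
  seed: 2021
filter:
  min_n: 3
  per_site: true
mantel:
  n_permutations: 999
  alternative: less
  indices: [jaccard, bray_curtis, morisita_horn]
  guild_scopes: [all, exposed, shelter]
  seed: 11
dsi:
  n_iterations: 499
  weighting: interaction_counts
  seed: 12
models:
  enabled: true
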