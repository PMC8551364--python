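# Example configuration for the `ragut` CLI.
# `ragut simulate --config config.yaml --out inputs/` writes the input files;
# the stage commands and `ragut run-all` then read them via `paths:`.

analysis:
  alpha: 0.05
  reporter_threshold: 1.65
  n_permutations: 9999
  fdr_method: bh
  rng_seed: 1
  pseudocount: 1.0e-6
  prevalence_min: 0.1   # 0 disables the prevalence filter

simulation:
  n_hc: 22
  n_ra: 22
  n_hqt: 13
  n_lef: 9
  n_species: 200
  n_genera: 40
  n_pathways: 60
  n_kos: 600
  enterotype_fraction_prevotella: 0.2
  n_spiked_up: 37
  n_spiked_down: 21
  effect_fold: 4.0
  restoration_rate_hqt: 0.15
  restoration_rate_lef: 0.04
  rng_seed: 1

paths:
  clinical: inputs/clinical.tsv
  species: inputs/species_profile.tsv
  pathways: inputs/pathway_abundance.tsv
  kos: inputs/gene_families.tsv
  kegg_map: inputs/kegg_map.tsv
  origin: inputs/origin.tsv
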