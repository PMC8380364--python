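# Full pipeline on a simulated cohort: microlmp run --config examples/pipeline_config.yaml
# Replace the `simulate` block with otu_table / taxonomy / metadata paths
# to run on real TSV inputs instead.
outdir: pipeline_out
seed: 1
simulate:
  n_samples: 300
  n_taxa: 80
  sequencing_depth: 20000
  # heavy dropout blunts SparCC badly (zeros become extreme log-ratio
  # outliers); keep it light so the planted blocks stay visible
  zero_inflation: 0.02
  correlation_blocks:
    - [[0, 1, 2, 3, 4], 0.7]
    - [[5, 6, 7, 8, 9], 0.7]
  enterotype_components:
    - [0.6, [60, 61, 62], 15.0]
    - [0.4, [65, 66, 67], 15.0]
  effect_taxa:
    - [20, 2.0, 0.0]
    - [21, 0.0, 1.0]
  batch_effects: [0.0, 0.8, -0.5]
# association stage (production thresholds)
assoc_min_abundance: 0.0005   # mean relative abundance > 0.05%
assoc_min_prevalence: 0.01    # present in > 1% of pigs
permutations: 1000
fdr_threshold: 0.01
# enterotype stage
enterotype_rank: genus
k_min: 2
k_max: 6
# CAG stage
cag_min_abundance: 0.001      # > 0.1% for CAG construction
n_cags: 3                     # or omit to scan with PERMANOVA
permanova_permutations: 1000
sparcc_resamples: 20
# network stage
edge_rule: threshold
edge_tau: 0.5
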