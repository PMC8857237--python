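# Replay configuration: a synthetic bundle whose planted truth reproduces the
# published candidate-funnel structure at desk scale.
#
# Stage structure encoded here (not in pipeline logic):
#   - 2993 genes unique to the two target genomes among 19 genomes total;
#   - exactly 7 of the unique genes unexpressed (zero mapped counts);
#   - 10 core biosynthetic genes among the unique+expressed set: the 5-gene
#     PKS-NRPS cluster template plus one additional distant 5-gene cluster;
#   - 7 complete-loss mutants with causal hits split 5 (T1-PKS) / 2 (NRPS),
#     2 reduced-activity mutants, Poisson(4) background mutation load, and
#     3 shared artifact substitutions in insertion-sequence genes.
seed: 1
n_genomes: 19
target_ids: [VT1065, BAM582]
n_core: 1500
n_shell: 800
n_unique: 2993
n_target_partial: 120
n_near_unique: 80
nb_mean: 250.0
nb_dispersion: 2.0
n_zero_expression: 7
n_filler_genes: 60
n_short_hypothetical: 6
n_is_elements: 3
n_extra_core_clusters: 1
mutation_lambda: 4.0
n_lost: 7
n_reduced: 2
n_wt: 1
causal_split: [5, 2]
n_artifact_variants: 3
spectrum:
  onset_temp_c: -4.0
  k_onset_per_cfu: 1.0e-07
  log10_slope_per_degree: 0.5
protocol:
  n_drops: 30
  n_dilutions: 6
  n_replicates: 3
  start_cfu_per_ml: 1.0e+08
  drop_volume_ul: 20.0
  temp_start_c: -2.0
  temp_stop_c: -12.0
  temp_step_c: 1.0
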