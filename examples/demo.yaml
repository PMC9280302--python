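# End-to-end demo: synthetic 12+12 cohort with the calibrated striatal
# atrophy effect and one planted metabolic-connectivity difference.
out_dir: demo_run
seed: 7
n_permutations: 1000
alpha: 0.05
simulate:
  n_per_group: {ich: 12, sham: 12}
  volume:
    group_effects:
      - [ich, striatum_r, 0.66]
      - [sham, striatum_r, 0.97]
  suv:
    planted_edges:
      - [striatum_l, striatum_r, sham, 0.85]
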