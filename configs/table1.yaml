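# Equal cluster sizes, 3 views of 150 nodes, P1-P4, 50 replicates.
output_dir: results/table1
seed: 1
replicates: 50
n_clusters: 3
beta_couple: 1.0
prob_matrices: [P1, P2, P3, P4]
cluster_sizes_per_view:
  - [50, 50, 50]
  - [50, 50, 50]
  - [50, 50, 50]
prob_scale_n: 150
solver:
  beta_pen: auto
  radius_factor: 1.04
  stepsize_rule: ABB
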