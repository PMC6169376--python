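schema_version: 1
seed: 3
genome_length: 5000000
n_chroms: 2
tree_root: REF
tree_branches:
- - REF
  - anc
  - 1.0
- - anc
  - p1
  - 1.0
- - anc
  - p2
  - 1.0
- - p1
  - B10
  - 1.0
- - p1
  - I03
  - 1.0
- - p2
  - ZH26
  - 2.0
- - p2
  - p3
  - 1.0
- - p3
  - N15
  - 1.0
- - p3
  - T29
  - 1.0
rate_per_branch: 40.0
sv_size_range:
- 50
- 10000
inversion_size_range:
- 12000
- 30000
type_weights:
  insertion: 0.3
  deletion: 0.3
  tandem_expansion: 0.085
  tandem_contraction: 0.085
  repeat_expansion: 0.085
  repeat_contraction: 0.085
  inversion: 0.06
min_locus_gap: 2000
tandem_array_count: 260
dispersed_repeat_count: 20
n_genes: 600
exons_per_gene:
- 2
- 6
exon_length:
- 100
- 500
motif: CACGAG
miss_prob: 0.1
false_per_100kb: 1.0
sizing_cv: 0.005
min_size: 50
max_size: 50000
min_match: 500
min_cluster_match: 100
map_min_size: 1000
tol: 3
inversion_min_size: 10000
k: 21
max_gap: 50000
band: 10
map_match_reward: 1.0
map_skip_penalty: 0.25
map_jump_penalty: 1.5
map_sizing_tol_bp: 100
map_sizing_tol_rel: 0.02
bootstrap_B: 1000
bootstrap_scales:
- 0.5
- 0.6
- 0.7
- 0.8
- 0.9
- 1.0
- 1.1
- 1.2
- 1.3
- 1.4
divergence_my: 1.0
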