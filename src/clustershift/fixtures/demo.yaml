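# Packaged synthetic demo: one tissue arm, planted premature shifts.
outdir: clustershift_demo
seed: 0
tissue: soft_tissue
simulate:
  n_genes: 300
  tissues: [soft_tissue]
  frac_shifted: 0.1
  noise_sd: 0.25
  n_gene_sets: 12
  set_size_range: [10, 25]
  n_cell_types: 3
  signature_size: 15
clusters: 8
n_perm: 200
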