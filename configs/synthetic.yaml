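# Packaged synthetic study conditions: a desk-scale cohort with planted
# cis eQTLs, co-expression blocks, an ambiguous-name target database and
# a scale-free PPI with a planted seed module.  `minet run-all --config
# configs/synthetic.yaml --outdir out` runs the full workflow on it.
seed: 17

synth:
  n_samples: 200
  n_mirnas: 60
  n_genes: 300
  n_true_eqtls: 20
  effect_size: 1.0
  noise_sd: 0.5
  mirna_block_sizes: [4, 4, 4, 4, 4, 4, 4, 4, 4, 4]
  gene_block_sizes: [5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5]
  block_rho: 0.8
  cis_fraction: 0.8
  ppi_edges: 3000

eqtl:
  window: 1000000
  fdr: 0.01

targets:
  ambiguous_fraction: 0.25

ppi:
  permutations: 1000
  alpha: 0.05

mtlasso:
  lam: auto
  gamma1: auto
  gamma2: auto
  corr_threshold: 0.7
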