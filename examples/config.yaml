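# End-to-end run on a small synthetic dataset.
#   lncm6a run-all --config examples/config.yaml
outdir: results/example
seed: 7
rna_padj: 0.05
peak_fdr: 0.05
diff_fdr: 0.05
window: 100
step: 50
neighbor_k: 5
simulate:
  n_lnc: 30
  n_coding: 60
  chrom_length: 600000
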