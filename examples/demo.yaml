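# Demonstration run: small synthetic study, completes in well under a minute.
seed: 7
outdir: runs/demo
simulate:
  seed: 7
  n_chroms: 1
  n_genes: 80
  n_peaks: 160
  n_dmrs: 20
  n_dars: 20
  n_degs: 40
  n_cis_meth: 6
  n_trans_meth: 6
  n_cis_atac: 6
  n_trans_atac: 6
  n_meth_per_group: 4
  n_atac_per_group: 4
  n_rhythm_genes: 6
n_permutations: 100
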