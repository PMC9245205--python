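# Demo configuration: simulate a trio and run the full analysis.
outdir: scratch/pipeline_demo
seed: 1
simulate:
  n_genes: 300
  n_replicates: 3
  frac_ase: 0.3
  n_terms: 10
n_sim: 500
thresholds:
  deg_fdr: 0.01
  deg_lfc: 1.0
  ase_padj: 0.05
  active_min_reads: 2
  active_min_reps: 2
  ase_min_depth: 10
flags:
  dghp_union: true
  rank_sum_sign_fix: true
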