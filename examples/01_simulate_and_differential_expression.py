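"""Simulate a parent/parent/hybrid trio and call differential expression.

Generates NB-distributed counts for a mother, father and F1 hybrid
(2 tissues x 3 replicates), then runs the hybrid-vs-mother NB Wald test.
A gene is a DEG at FDR <= 0.01 and |log2FC| >= 1.
"""

import heteroseq as h

cfg = h.SimConfig(seed=1, n_genes=1000)
cm, truth = h.simdata.simulate_trio_counts(cfg)
print(f"counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples")

active = h.diffexpr.call_active_genes(cm, cm.sample_ids(accession="F1", tissue="leaf"))
print(f"actively expressed genes in hybrid leaf (>=2 reads in >=2 reps): {len(active)}")

res = h.diffexpr.nb_wald_test(cm,
                              cm.sample_ids(role="maternal", tissue="leaf"),
                              cm.sample_ids(role="hybrid", tissue="leaf"))
n_deg = int(res["is_deg"].sum())
up = int((res.loc[res["is_deg"], "direction"] == "up").sum())
print(f"hybrid-vs-mother DEGs in leaf: {n_deg} ({up} up in the hybrid)")
print(res[res["is_deg"]].head(3).to_string(index=False))
print("-> each row: normalized group means, log2 fold change, Wald stat, "
      "raw and BH-adjusted p; 'up' means higher in the hybrid.")
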