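"""Counts -> RPKM -> differential expression on a synthetic cohort.

Simulates raw counts, converts to RPKM, runs the case/control test and
applies the upregulation filter (fold change >= 1.5, FDR < 0.05); the
planted signature genes should dominate the upregulated set.
"""

import ifnsig

cfg = ifnsig.CohortConfig(value_kind="counts")
matrix, samples, truth = ifnsig.generate_cohort(cfg, seed=0)
rpkm = ifnsig.counts_to_rpkm(matrix)

de = ifnsig.de_test(rpkm, samples, "GPP", "healthy")
up = ifnsig.filter_upregulated(de, fc_threshold=1.5, fdr_threshold=0.05)
top = ifnsig.top_n_by_significance(de, n=10)

planted = set(truth.gene_fold)
print(f"{len(up)} upregulated genes (fc >= 1.5, FDR < 0.05); "
      f"{len(up & planted)} of the {len(planted)} planted genes recovered")
print("top genes by significance (gene, fold change, FDR):")
for g in top:
    row = de.loc[g]
    marker = "*" if g in planted else " "
    print(f"  {marker} {g:10s} {row.fold_change:6.2f}  {row.fdr:.3g}")
print("(* = planted signature gene)")
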