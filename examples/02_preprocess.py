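"""Preprocess raw single-cell expression for the link predictor.

Applies the fixed pipeline: detection filter (genes expressed in >= 10%
of cells), chi-square dispersion screen with Bonferroni correction
(keep significant TFs plus the top-k most variable genes), then log2(x+1).
"""

from reglink import make_fixture, preprocess_pipeline

x, net, _ = make_fixture("strong_signal")
xp, sel = preprocess_pipeline(x, net.tf_set, min_cell_fraction=0.10,
                              alpha=0.01, top_k=500)

n_sig = int((sel.pvalues * len(sel.gene_ids) < sel.alpha).sum())
print(f"input genes: {x.n_genes}; tested: {len(sel.gene_ids)}; "
      f"Bonferroni-significant: {n_sig}")
print(f"kept genes (significant TFs + top-k variable): {xp.n_genes}")
print(f"kept TFs: {len(set(xp.gene_ids) & net.tf_set)} of {len(net.tf_set)}")
print(f"value range after log2(x+1): [{xp.values.min():.2f}, {xp.values.max():.2f}]")
# Genes that fail the variability screen carry little information about
# regulation; dropping them shrinks the candidate-edge space accordingly.
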