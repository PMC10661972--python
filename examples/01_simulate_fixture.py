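"""Plant a synthetic regulatory network and simulate matched expression.

Builds the 'strong_signal' preset (25 TFs, 200 genes, 300 cells, edge
density 0.05, dropout 0.2) and prints its realised size.  The planted
edges are the ground truth every later stage is scored against.
"""

from reglink import make_fixture

x, net, paths = make_fixture("strong_signal", out_dir="scratch/fixture")

print(f"expression matrix: {x.n_genes} genes x {x.n_cells} cells")
print(f"zero fraction (dropout + softplus floor): {(x.values == 0).mean():.3f}")
print(f"planted network: {len(net.edges)} TF->target edges, "
      f"{len(net.tf_set)} TFs, density {net.density:.4f}")
print(f"files written: {sorted(p.name for p in paths.values())}")
# The density is the fraction of possible TF->gene pairs that are true
# edges; it sets the chance level (prevalence) of the evaluation below.
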