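"""Rank every candidate TF->gene pair by predicted regulatory score.

After training, the decoder assigns a nonnegative score to every gene
pair; restricting to TF->gene candidates outside the training positives
gives the ranked edge list a user would follow up experimentally.
"""

from reglink import TrainConfig, make_fixture, rank_candidates, run_pipeline

x, net, _ = make_fixture("smoke")
model, history, split, scores, report, xp = run_pipeline(x, net, TrainConfig(seed=1))

net_kept = net.restrict(xp.gene_ids)
ranked = rank_candidates(scores, net_kept, exclude=split.train_pos)
held_out = split.val_pos | split.test_pos

print(f"candidates ranked: {len(ranked)}")
print("top 5 predictions (source, target, score, is-true-edge):")
for s, t, w in ranked[:5]:
    print(f"  {s:>5} -> {t:<5} {w:8.4f}  {'TRUE' if (s, t) in held_out else '?'}")
# 'TRUE' marks held-out planted edges the model never saw as labels;
# '?' pairs are either non-edges or undiscovered regulation.
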