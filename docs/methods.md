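# Methods

## Model

`reglink` treats GRN inference as supervised link prediction. The inputs
are a nonnegative gene × cell expression matrix X (N genes, M cells) and
a directed prior network G = (V, ξ) of known TF → target edges over the
same genes, with a designated TF set (only TFs may be edge sources).

**Encoder.** L stacked graph-convolution layers

    H⁽ˡ⁾ = ReLU( P · H⁽ˡ⁻¹⁾ · W⁽ˡ⁻¹⁾ + b⁽ˡ⁻¹⁾ ),  P = λ·Ã + (1−λ)·I,  H⁽⁰⁾ = X

with Ã = D^{−1/2}(A + I)D^{−1/2}, where A is the *symmetrised* binary
adjacency of the prior edges and D its self-looped degree matrix. The
symmetric normalisation keeps the operator's spectral radius ≤ 1, so
repeated propagation cannot blow up. Directionality is not lost: labels
and candidate enumeration stay directed TF → gene; only message passing
is bidirectional. The mixing coefficient λ interpolates between a pure
feature model (λ=0: the graph is ignored) and pure graph smoothing (λ=1:
the standard GCN propagation rule).

**Decoder.** R = ReLU(H Hᵀ): the regulatory score of a pair is the inner
product of the two genes' embeddings. Because the last encoder layer ends
in a ReLU, H ≥ 0 and the decoder rectification is inactive for trained
models; it matters only for externally supplied embeddings. R is
symmetric, so the decoder cannot distinguish i→j from j→i; the pipeline
compensates by scoring only TF → gene candidates. This is a known
structural limitation, not a bug.

**Loss and optimisation.** Over labelled pairs Ω⁺ ∪ Ω⁻ (positives 1,
negatives 0),

    ℓ = mean_{(i,j)} (R(i,j) − y_{ij})² + weight_decay · Σ_l ‖W⁽ˡ⁾‖²_F

optimised full-batch with Adam. At the problem sizes this package targets
(N ≲ 1500) minibatching would only add variance. Biases are not
regularised. Training runs the full epoch budget; the parameters from the
epoch with the highest validation AUROC are returned, which reconciles a
fixed schedule with validation-based model selection.

## Labelling protocol

* **Positive split** — known edges are partitioned 3:1:1 into
  train/validation/test uniformly at random; integer remainders are
  assigned train-first, then validation. Fewer than five positives is an
  error.
* **Training negatives** — *hard* negatives: for each positive (g1, g2),
  `ceil(neg_ratio)` unobserved pairs (g1, g3) sharing the source TF are
  drawn uniformly (default ratio 1.0). If a TF's pool is exhausted the
  draw falls back to the unrestricted pool. Hard negatives force the
  model to discriminate among a TF's potential targets rather than merely
  recognising active TFs.
* **Validation/test negatives** — uniform unobserved (TF, gene) pairs at
  a count matching the network density ρ = |ξ| / (|TF|·(N−1)), i.e.
  `round(n_pos · (1−ρ)/ρ)` per set, so evaluation prevalence equals ρ.
  Validation mirrors the test protocol (rather than the training
  protocol) so the per-epoch validation AUROC estimates the quantity the
  test set measures. All negative sets are disjoint from each other and
  from every positive.
* **Leakage control** — the message-passing adjacency is built from
  *training* positives only; validation and test edges never reach the
  encoder.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epochs` | 200 | full-batch Adam updates |
| `learning_rate` | 0.005 | Adam step size |
| `lambda_mix` | 0.4 | graph-vs-features mixing in the encoder |
| `weight_decay` | 5e-4 | Frobenius penalty on weights |
| `neg_ratio` | 1.0 | hard negatives per training positive |
| `hidden_dims` | (256, 128) | layer widths; d₁ = 128 is the embedding size |
| `min_cell_fraction` | 0.10 | detection filter threshold |
| `alpha` | 0.01 | Bonferroni-corrected significance level |
| `top_k` | 500 | variable genes kept beyond significant TFs |

## Preprocessing

Fixed order: (1) drop genes detected (value > 0) in fewer than 10% of
cells — a gene at exactly the threshold is kept; (2) per-gene sample
variance (denominator M−1) with a chi-square dispersion p-value: the
statistic (M−1)·var_g / median(var) is referred to χ²_{M−1} and the
upper-tail probability taken. The dispersion-against-the-median screen is
a standard highly-variable-gene test; it is exposed as a strategy so a
rank-only top-k selection can replace it. (3) Bonferroni correction over
the genes actually tested; keep all significant TFs plus the `top_k` most
variable significant genes, ordered by descending variance. (4)
log2(x + 1) — base 2 is the dominant convention for expression data and
is configurable.

`perturb_expression` adds seeded Gaussian noise clamped at zero, for
robustness experiments; it is not part of the standard pipeline.

## Numerical choices

* **Input-scale calibration.** Glorot-uniform weights on nonnegative
  log-expression features give initial pair scores of order 10–100 —
  far above the 0/1 labels. With the fixed learning rate, the resulting
  MSE gradients drive most ReLU units permanently inactive within a few
  epochs (dead-unit lockout) and the model never recovers. Training
  therefore calibrates a single fixed input scale before the first
  update: with zero initial biases the encoder is positively homogeneous,
  so scores scale quadratically in the input, and the scale is set so the
  initial training-pair score RMS is 0.5, the midpoint of the labels. The
  scale is stored in the model (`input_scale`) and applied identically at
  inference; weights themselves remain at Glorot magnitude, where the
  default Adam step is well-proportioned.
* ReLU subgradient at exactly 0 is taken as 0 throughout (forward zero,
  backward zero); analytic gradients match central finite differences to
  1e-4 relative error (tested).
* Ranked-edge output sorts by score descending with (source, target)
  lexicographic tie-breaks, so outputs are byte-reproducible.
* Expression CSVs are written with `%.17g` and parsed with correctly
  rounded float conversion, so write/read round trips are exact.
* Isolated nodes in the adjacency reduce to a unit self-loop row.
* All sub-seeds (split, negative sampling, initialisation) derive from
  one user seed via `numpy.random.SeedSequence`.

## Synthetic data generator

The generator provides ground truth for every stage without downloads.
`simulate_grn` plants directed TF → gene edges i.i.d. at a configured
density, with per-TF lognormal activity multipliers (σ = 0.8, normalised
to mean 1) tilting out-degrees so hub TFs exist without changing the
expected density. `simulate_expression` draws per-cell TF activities
|N(0,1)|, fixed per-edge weights N(0, edge_weight_scale²) with
edge_weight_scale = 1 — order-one regulatory effects on the activity
scale — and sets a target's expression to softplus(Σ w·activity) plus
half-normal measurement noise; TFs express their own activity plus
noise; finally every entry is zeroed independently with the dropout
probability, emulating missed detection in single-cell capture.

Presets (pinned seeds): `smoke` (10 TFs / 50 genes / 100 cells / density
0.05), `strong_signal` (25 / 200 / 300 / 0.05, noise sd 0.1, dropout
0.2), `dense` (15 / 100 / 200 / 0.4, emulating the high densities of
cell-type-specific ChIP-seq ground truths). The smoke and dense presets
reuse the strong-signal noise and dropout levels.

**What the generator does and does not emulate.** It reproduces the
statistical structure the method relies on — co-variation of targets
with their regulators' activities, heavy-tailed TF out-degrees, dropout
zeros, nonnegativity — at trivial cost. It does not model kinetics,
cell-type mixtures, trajectories, batch effects, magnitude-dependent
dropout, or indirect/chained regulation. Passing tests on these fixtures
therefore demonstrate correctness of the pipeline and recovery of
linear-SEM-style signal, not performance on real scRNA-seq data.

Two properties of the generator deserve emphasis when interpreting
end-to-end numbers. First, signed edge weights pass through softplus, so
roughly half the planted edges act on its flat side and leave only a
weak (sometimes statistically invisible) trace in expression — planted
density overstates *recoverable* density. Second, with a few hundred
labelled pairs and ~10⁵ encoder parameters, the model can fit the
training labels long before it has learned transferable structure;
validation-based checkpoint selection, the hard-negative contrast and
the Frobenius penalty are the only countervailing forces. Both effects
cap held-out ranking performance on the synthetic conditions well below
what the same architecture reports on large, dense real benchmarks, and
the acceptance script's numbers should be read with that in mind.

## Known limitations

* The symmetric decoder cannot represent edge direction; candidate
  restriction to TF → gene pairs sidesteps but does not solve this.
* Nonnegative embeddings (final ReLU) make the score an inner product of
  nonnegative vectors; similarity that depends on the *magnitude* of
  signed correlation is not exactly representable.
* No activation/repression edge types, no attention, no imputation
  (externally imputed matrices are accepted through the same reader),
  no batch correction, no cell filtering.
* Full-batch dense linear algebra: memory is O(N²); designed for the
  TF + top-k-variable-genes regime, not whole-transcriptome graphs.
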