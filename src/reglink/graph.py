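"""Message-passing adjacency, edge splitting and negative sampling.

The prior TF -> target network plays two roles that this module keeps
separate:

* as the *message-passing graph* of the encoder it is symmetrised, given
  self-loops, and degree-normalised (``D^{-1/2} (A + I) D^{-1/2}``) — built
  from **training positives only** so that held-out edges never leak into
  the features;
* as the *label source* it stays directed: positives are split 3:1:1 into
  train/validation/test, and 0-labelled negatives are sampled from
  unobserved TF -> gene pairs.

Training (and validation) negatives are *hard*: each positive (g1, g2) is
paired with negatives (g1, g3) sharing the same source TF.  Test negatives
are sampled uniformly at a count matching the network density, so test
prevalence equals the density of the prior network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ReglinkError
from .io import PriorNetwork

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetric degree-normalised adjacency with self-loops over ``node_ids``."""

    matrix: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", a)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ReglinkError(f"adjacency shape {a.shape} does not match {n} nodes")
        if not np.allclose(a, a.T):
            raise ReglinkError("normalized adjacency must be symmetric")
        if np.any(np.diag(a) <= 0):
            raise ReglinkError("normalized adjacency must have positive diagonal (self-loops)")


@dataclass(frozen=True)
class EdgeSplit:
    """Labelled positive/negative pairs partitioned into train/val/test."""

    train_pos: frozenset[Pair]
    val_pos: frozenset[Pair]
    test_pos: frozenset[Pair]
    train_neg: frozenset[Pair] = field(default_factory=frozenset)
    val_neg: frozenset[Pair] = field(default_factory=frozenset)
    test_neg: frozenset[Pair] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        pos_sets = [self.train_pos, self.val_pos, self.test_pos]
        neg_sets = [self.train_neg, self.val_neg, self.test_neg]
        all_pos = set().union(*pos_sets)
        if sum(len(s) for s in pos_sets) != len(all_pos):
            raise ReglinkError("positive splits must be disjoint")
        all_neg = set().union(*neg_sets)
        if sum(len(s) for s in neg_sets) != len(all_neg):
            raise ReglinkError("negative splits must be disjoint")
        if all_neg & all_pos:
            raise ReglinkError("negatives must be disjoint from positives")

    @property
    def all_positives(self) -> frozenset[Pair]:
        return self.train_pos | self.val_pos | self.test_pos


def build_normalized_adjacency(
    net: PriorNetwork,
    nodes: Sequence[str],
    edge_subset: set[Pair] | frozenset[Pair],
) -> NormalizedAdjacency:
    """Build ``D^{-1/2} (A + I) D^{-1/2}`` from a directed edge subset.

    ``A`` is the binary *symmetrised* adjacency of ``edge_subset`` (an edge
    in either direction sets both entries) plus identity self-loops, and
    ``D`` holds its row sums.  Isolated nodes reduce to a unit self-loop.
    """
    if not set(edge_subset) <= set(net.edges):
        raise ReglinkError("edge_subset must be a subset of the network's edges")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    a = np.eye(n)
    for s, t in edge_subset:
        if s not in index or t not in index:
            raise ReglinkError(f"edge ({s},{t}) has an endpoint outside the node list")
        a[index[s], index[t]] = 1.0
        a[index[t], index[s]] = 1.0
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return NormalizedAdjacency(a * np.outer(inv_sqrt, inv_sqrt), tuple(nodes))


def _split_counts(n: int) -> tuple[int, int, int]:
    """3:1:1 counts with remainder assigned train-first (train, val, test)."""
    n_train, n_val, n_test = (3 * n) // 5, n // 5, n // 5
    for _ in range(n - (n_train + n_val + n_test)):
        if n_train < math.ceil(3 * n / 5):
            n_train += 1
        elif n_val < math.ceil(n / 5):
            n_val += 1
        else:
            n_test += 1
    return n_train, n_val, n_test


def split_positives(net: PriorNetwork, seed: int) -> EdgeSplit:
    """Uniformly partition the known positive edges 3:1:1 (train/val/test).

    Deterministic given ``seed``; remainders go to train first, then
    validation.  Fewer than five positives is a hard error.
    """
    edges = sorted(net.edges)
    n = len(edges)
    if n < 5:
        raise ReglinkError(f"need at least 5 positive edges to split 3:1:1, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val, _ = _split_counts(n)
    train = frozenset(edges[i] for i in perm[:n_train])
    val = frozenset(edges[i] for i in perm[n_train:n_train + n_val])
    test = frozenset(edges[i] for i in perm[n_train + n_val:])
    return EdgeSplit(train, val, test, seed=seed)


def sample_hard_negatives(
    positives: set[Pair] | frozenset[Pair],
    all_edges: set[Pair] | frozenset[Pair],
    net: PriorNetwork,
    ratio: float,
    seed: int,
    exclude: set[Pair] | frozenset[Pair] = frozenset(),
) -> frozenset[Pair]:
    """Sample hard negatives: unobserved (TF, gene) pairs sharing the source
    TF of a positive.

    For each positive ``(g1, g2)``, ``ceil(ratio)`` candidates are drawn
    uniformly from ``{(g1, g3): g3 != g1, (g1, g3) not a true edge}``; if
    that source-restricted pool is exhausted the draw falls back to the
    unrestricted pool over all TFs.  No duplicates are returned, nothing in
    ``exclude`` or ``all_edges`` is returned, and the result is
    deterministic given ``seed``.  If every pool is exhausted the sampler
    stops early with a logged warning.
    """
    if ratio <= 0:
        raise ReglinkError("negative sampling ratio must be > 0")
    per_pos = math.ceil(ratio)
    rng = np.random.default_rng(seed)
    genes = list(net.genes)
    tfs = sorted(net.tf_set)
    forbidden = set(all_edges) | set(exclude)
    taken: set[Pair] = set()
    exhausted = False
    for g1, _ in sorted(positives):
        for _ in range(per_pos):
            pool = [
                (g1, g3) for g3 in genes
                if g3 != g1 and (g1, g3) not in forbidden and (g1, g3) not in taken
            ]
            if not pool:
                pool = [
                    (s, g3) for s in tfs for g3 in genes
                    if g3 != s and (s, g3) not in forbidden and (s, g3) not in taken
                ]
            if not pool:
                exhausted = True
                break
            taken.add(pool[int(rng.integers(len(pool)))])
        if exhausted:
            break
    if exhausted:
        logger.warning(
            "sample_hard_negatives: candidate pool exhausted after %d of %d requested negatives",
            len(taken), per_pos * len(positives),
        )
    return frozenset(taken)


def density_matched_test_negatives(
    test_pos: set[Pair] | frozenset[Pair],
    net: PriorNetwork,
    seed: int,
    exclude: set[Pair] | frozenset[Pair] = frozenset(),
) -> frozenset[Pair]:
    """Sample uniform negatives at a count matching network density.

    With density ``rho = |edges| / (|tf_set| * (|genes| - 1))`` the count is
    ``round(|test_pos| * (1 - rho) / rho)`` so that test-set prevalence
    equals ``rho``.  Negatives are drawn without replacement from all
    unobserved (TF, gene) pairs, excluding every positive and anything in
    ``exclude``; a pool smaller than the request is used in full with a
    logged warning.
    """
    rho = net.density
    count = round(len(test_pos) * (1.0 - rho) / rho)
    forbidden = set(net.edges) | set(exclude)
    pool = sorted(
        (s, t) for s in net.tf_set for t in net.genes
        if t != s and (s, t) not in forbidden
    )
    if count > len(pool):
        logger.warning(
            "density_matched_test_negatives: pool has %d pairs, %d requested", len(pool), count
        )
        count = len(pool)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=count, replace=False)
    return frozenset(pool[i] for i in chosen)


def make_split(net: PriorNetwork, seed: int, neg_ratio: float = 1.0) -> EdgeSplit:
    """Full labelled split: 3:1:1 positives, hard training negatives at
    ``neg_ratio`` per positive, and density-matched uniform validation and
    test negatives.

    Validation negatives follow the test protocol (uniform, density
    matched) rather than the training protocol (hard) so that the
    validation AUROC used for checkpoint selection estimates the quantity
    the test set measures.  All three negative sets are disjoint from each
    other and from every positive; sub-seeds are derived from ``seed`` so
    the whole split is reproducible from one integer.
    """
    sub = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    split = split_positives(net, seed=int(sub[0]))
    train_neg = sample_hard_negatives(
        split.train_pos, net.edges, net, neg_ratio, seed=int(sub[1])
    )
    val_neg = density_matched_test_negatives(
        split.val_pos, net, seed=int(sub[2]), exclude=train_neg
    )
    test_neg = density_matched_test_negatives(
        split.test_pos, net, seed=int(sub[3]), exclude=train_neg | val_neg
    )
    return EdgeSplit(
        split.train_pos, split.val_pos, split.test_pos,
        train_neg, val_neg, test_neg, seed=seed,
    )
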