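"""Ranking metrics and candidate-edge ranking.

AUROC is the probability that a random positive outranks a random negative
(ties counted 1/2, i.e. the normalised Mann-Whitney U); AUPRC is the
step-wise (interpolation-free) area under the precision-recall curve, whose
chance level equals the positive prevalence.  Both delegate to
scikit-learn, which implements exactly these conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ReglinkError
from .graph import Pair
from .io import PriorNetwork
from .model import ScoreMatrix, score_pairs


@dataclass(frozen=True)
class MetricsReport:
    """AUROC/AUPRC on a labelled pair set, with class counts and prevalence."""

    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    prevalence: float

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ReglinkError("scores and labels must be equal-length 1-D sequences")
    if not set(np.unique(y)) <= {0, 1}:
        raise ReglinkError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ReglinkError("both classes must be present to compute a ranking metric")
    return s, y


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank probability with ties at 1/2)."""
    s, y = _validate(scores, labels)
    return float(roc_auc_score(y, s))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise area under the precision-recall curve (average precision)."""
    s, y = _validate(scores, labels)
    return float(average_precision_score(y, s))


def evaluate_pairs(
    r: ScoreMatrix,
    positives: Sequence[Pair] | frozenset[Pair],
    negatives: Sequence[Pair] | frozenset[Pair],
) -> MetricsReport:
    """Score the given positive/negative pairs from ``r`` and report metrics."""
    pos = sorted(positives)
    neg = sorted(negatives)
    if not pos or not neg:
        raise ReglinkError("evaluation needs at least one positive and one negative pair")
    scores = np.concatenate([score_pairs(r, pos), score_pairs(r, neg)])
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return MetricsReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        n_pos=len(pos),
        n_neg=len(neg),
        prevalence=len(pos) / (len(pos) + len(neg)),
    )


def rank_candidates(
    r: ScoreMatrix,
    net: PriorNetwork,
    exclude: set[Pair] | frozenset[Pair] = frozenset(),
) -> list[tuple[str, str, float]]:
    """Rank all candidate TF -> gene pairs by score, descending.

    Candidates are every ``(tf, gene)`` with ``tf`` in the TF set,
    ``gene != tf`` and the pair not in ``exclude`` (typically the training
    positives).  Ties are broken by (source, target) lexicographic order.
    """
    index = r.index()
    out: list[tuple[str, str, float]] = []
    for tf in sorted(net.tf_set):
        i = index.get(tf)
        if i is None:
            raise ReglinkError(f"TF {tf!r} is not a node of the score matrix")
        for gene in net.genes:
            if gene == tf or (tf, gene) in exclude:
                continue
            out.append((tf, gene, float(r.matrix[i, index[gene]])))
    out.sort(key=lambda p: (-p[2], p[0], p[1]))
    return out
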