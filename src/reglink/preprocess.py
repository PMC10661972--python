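"""Expression preprocessing: filtering, variable-gene selection, normalisation.

The pipeline mirrors the standard supervised-GRN preparation of single-cell
expression data and runs in a fixed order:

1. :func:`filter_low_expression` — drop genes detected (value > 0) in less
   than a given fraction of cells (default 10%);
2. :func:`variance_significance` — per-gene sample variance plus a
   chi-square dispersion p-value against the dataset median variance;
3. :func:`select_genes` — Bonferroni-corrected significance screen, then
   keep all significant TFs plus the ``top_k`` most variable genes;
4. :func:`log_normalize` — entrywise log(x + 1) (base 2 by default).

:func:`perturb_expression` is a separate utility that injects seeded
Gaussian noise for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ReglinkError
from .io import ExpressionMatrix


@dataclass(frozen=True)
class GeneSelection:
    """Per-gene variance statistics for the genes that entered the screen."""

    gene_ids: tuple[str, ...]
    variances: np.ndarray  # sample variance (ddof=1), >= 0
    pvalues: np.ndarray  # chi-square dispersion p-value, in [0, 1]
    min_cell_fraction: float
    alpha: float | None = None
    top_k: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.variances, dtype=np.float64)
        p = np.asarray(self.pvalues, dtype=np.float64)
        object.__setattr__(self, "variances", v)
        object.__setattr__(self, "pvalues", p)
        n = len(self.gene_ids)
        if v.shape != (n,) or p.shape != (n,):
            raise ReglinkError("variance/p-value arrays must align with gene_ids")
        if np.any(v < 0):
            raise ReglinkError("variances must be nonnegative")
        if np.any((p < 0) | (p > 1)):
            raise ReglinkError("p-values must lie in [0, 1]")


def filter_low_expression(
    x: ExpressionMatrix, min_cell_fraction: float = 0.10
) -> ExpressionMatrix:
    """Drop genes detected in fewer than ``min_cell_fraction`` of cells.

    "Detected" means value > 0.  A gene is *removed* when its detected
    fraction is strictly below the threshold, so a gene at exactly the
    threshold is kept.  Gene order is preserved.  Removing every gene is
    a hard error.  The operation is idempotent.
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ReglinkError("min_cell_fraction must lie in [0, 1]")
    frac = (x.values > 0).mean(axis=1)
    keep = [g for g, f in zip(x.gene_ids, frac) if f >= min_cell_fraction]
    if not keep:
        raise ReglinkError(
            f"all {x.n_genes} genes fall below the {min_cell_fraction:.0%} detection threshold"
        )
    return x.subset_genes(keep)


def variance_significance(x: ExpressionMatrix) -> GeneSelection:
    """Per-gene variance and a chi-square dispersion p-value.

    For each gene the sample variance (denominator M-1) is tested against
    the dataset median variance with the dispersion statistic
    ``s = (M-1) * var_g / median_var`` referred to a chi-square
    distribution with M-1 degrees of freedom; the p-value is the upper
    tail P(chi2_{M-1} >= s).  A constant gene has variance 0 and p = 1.
    All genes constant (median variance 0) is a hard error.
    """
    m = x.n_cells
    if m < 2:
        raise ReglinkError("variance test requires at least two cells")
    variances = x.values.var(axis=1, ddof=1)
    median_var = float(np.median(variances))
    if median_var == 0.0:
        raise ReglinkError("median gene variance is zero; cannot form the dispersion statistic")
    statistic = (m - 1) * variances / median_var
    pvalues = stats.chi2.sf(statistic, df=m - 1)
    return GeneSelection(x.gene_ids, variances, pvalues, min_cell_fraction=np.nan)


def select_genes(
    sel: GeneSelection,
    x: ExpressionMatrix,
    tf_set: set[str] | frozenset[str],
    alpha: float = 0.01,
    top_k: int = 500,
) -> ExpressionMatrix:
    """Keep Bonferroni-significant genes: all significant TFs plus the
    ``top_k`` most variable significant genes.

    The Bonferroni-adjusted p-value is ``min(1, p * N_tested)`` with
    ``N_tested`` the number of genes that entered the screen; genes with
    adjusted p < ``alpha`` are significant.  The returned matrix is
    ordered by descending variance (ties broken by gene ID).
    """
    if top_k < 1:
        raise ReglinkError("top_k must be >= 1")
    if sel.gene_ids != x.gene_ids:
        raise ReglinkError("GeneSelection gene order does not match the expression matrix")
    n_tested = len(sel.gene_ids)
    adjusted = np.minimum(1.0, sel.pvalues * n_tested)
    significant = adjusted < alpha
    if not significant.any():
        raise ReglinkError(
            f"no gene passes the Bonferroni screen at alpha={alpha}; try a larger alpha"
        )
    order = sorted(
        (i for i in range(n_tested) if significant[i]),
        key=lambda i: (-sel.variances[i], sel.gene_ids[i]),
    )
    top = set(order[:top_k])
    keep_idx = [i for i in order if i in top or sel.gene_ids[i] in tf_set]
    return x.subset_genes([sel.gene_ids[i] for i in keep_idx])


def log_normalize(x: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Entrywise ``log_base(value + 1)``; shape and identifiers unchanged.

    Strictly monotone and maps 0 to 0, so detection patterns survive.
    """
    if base <= 1.0:
        raise ReglinkError("log base must be > 1")
    values = np.log1p(x.values) / np.log(base)
    return ExpressionMatrix(x.gene_ids, x.cell_ids, values)


def perturb_expression(x: ExpressionMatrix, sigma: float, seed: int) -> ExpressionMatrix:
    """Add i.i.d. Normal(0, sigma^2) noise, clamped at zero.

    Used for robustness experiments that degrade the expression signal by
    a controlled amount; reproducible under a fixed seed.
    """
    if sigma < 0:
        raise ReglinkError("sigma must be >= 0")
    if sigma == 0:
        return x
    rng = np.random.default_rng(seed)
    noisy = np.maximum(x.values + rng.normal(0.0, sigma, size=x.values.shape), 0.0)
    return ExpressionMatrix(x.gene_ids, x.cell_ids, noisy)


def preprocess_pipeline(
    x: ExpressionMatrix,
    tf_set: set[str] | frozenset[str],
    min_cell_fraction: float = 0.10,
    alpha: float = 0.01,
    top_k: int = 500,
    log_base: float = 2.0,
) -> tuple[ExpressionMatrix, GeneSelection]:
    """Run the full fixed-order preprocessing pipeline.

    Returns the log-normalised, gene-selected matrix together with the
    :class:`GeneSelection` computed on the detection-filtered matrix.
    """
    filtered = filter_low_expression(x, min_cell_fraction)
    sel = variance_significance(filtered)
    sel = GeneSelection(
        sel.gene_ids, sel.variances, sel.pvalues,
        min_cell_fraction=min_cell_fraction, alpha=alpha, top_k=top_k,
    )
    selected = select_genes(sel, filtered, tf_set, alpha=alpha, top_k=top_k)
    return log_normalize(selected, base=log_base), sel
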