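"""Planted regulatory networks and matched synthetic scRNA-seq matrices.

The generator provides ground truth for every pipeline stage without any
external download.  It plants a directed TF -> target network at a chosen
density and then simulates expression with a linear-weights + softplus
structural model:

* each TF has a per-cell activity ``|Normal(0, 1)|``;
* each edge carries a fixed weight ``Normal(0, edge_weight_scale^2)``;
* a target's expression is ``softplus(sum_w w * activity_tf)`` plus
  half-normal measurement noise; TFs express their own activity plus noise;
* every entry is independently zeroed with probability ``dropout_rate``,
  emulating the false zeros of single-cell capture.

This yields exactly the statistical structure a supervised link predictor
exploits — co-variation of targets with their true regulators — while
remaining cheap and fully seeded.  TF out-degrees are tilted by lognormal
per-TF multipliers (normalised to mean 1) so hub TFs exist without
changing the expected density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ReglinkError
from .io import ExpressionMatrix, PriorNetwork, write_expression, write_network

#: sigma of the lognormal out-degree tilt (mean-normalised, so density-neutral)
_DEGREE_TILT_SIGMA = 0.8


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults match the mid-size benchmark regime."""

    n_tfs: int = 25
    n_genes: int = 200
    density: float = 0.05
    n_cells: int = 300
    edge_weight_scale: float = 1.0
    noise_sd: float = 0.1
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_tfs <= self.n_genes:
            raise ReglinkError("need 1 <= n_tfs <= n_genes")
        if not 0.0 < self.density < 1.0:
            raise ReglinkError("density must lie in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ReglinkError("dropout_rate must lie in [0, 1)")
        if self.n_cells < 1 or self.noise_sd < 0 or self.edge_weight_scale <= 0:
            raise ReglinkError("invalid synthetic configuration")


#: named fixture presets (sizes, density, noise) with pinned seeds
PRESETS: dict[str, SyntheticConfig] = {
    "smoke": SyntheticConfig(n_tfs=10, n_genes=50, n_cells=100, density=0.05,
                             noise_sd=0.1, dropout_rate=0.2, seed=11),
    "strong_signal": SyntheticConfig(n_tfs=25, n_genes=200, n_cells=300, density=0.05,
                                     noise_sd=0.1, dropout_rate=0.2, seed=42),
    "dense": SyntheticConfig(n_tfs=15, n_genes=100, n_cells=200, density=0.4,
                             noise_sd=0.1, dropout_rate=0.2, seed=7),
}


def _gene_names(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
    targets = [f"G{j + 1}" for j in range(cfg.n_genes - cfg.n_tfs)]
    return tfs, targets


def simulate_grn(cfg: SyntheticConfig) -> PriorNetwork:
    """Plant a directed TF -> gene network at the configured density.

    Each (tf, gene) pair (self-pairs excluded) is an edge with probability
    ``density * m_tf / mean(m)`` where the per-TF multipliers ``m`` are
    lognormal — heavy-tailed out-degrees at exactly the requested expected
    density.  Deterministic given ``cfg.seed``; drawing zero edges triggers
    one resample, then a hard error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    tfs, targets = _gene_names(cfg)
    genes = tfs + targets
    mult = rng.lognormal(mean=0.0, sigma=_DEGREE_TILT_SIGMA, size=cfg.n_tfs)
    p_tf = np.clip(cfg.density * mult / mult.mean(), 0.0, 1.0)
    for _attempt in range(2):
        edges = {
            (tf, g)
            for i, tf in enumerate(tfs)
            for g in genes
            if g != tf and rng.random() < p_tf[i]
        }
        if edges:
            return PriorNetwork(tuple(genes), frozenset(edges), frozenset(tfs))
    raise ReglinkError(
        f"no edges drawn at density {cfg.density} over {cfg.n_tfs}x{cfg.n_genes} pairs"
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_expression(net: PriorNetwork, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Simulate a nonnegative gene x cell matrix consistent with ``net``.

    See the module docstring for the structural model.  Gene order follows
    ``net.genes``; deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    tfs = [g for g in net.genes if g in net.tf_set]
    tf_row = {tf: k for k, tf in enumerate(tfs)}
    activities = np.abs(rng.normal(size=(len(tfs), cfg.n_cells)))
    weights = {e: rng.normal(0.0, cfg.edge_weight_scale) for e in sorted(net.edges)}

    values = np.zeros((len(net.genes), cfg.n_cells))
    incoming: dict[str, list[tuple[str, float]]] = {g: [] for g in net.genes}
    for (s, t), w in weights.items():
        incoming[t].append((s, w))
    for i, g in enumerate(net.genes):
        if g in net.tf_set:
            values[i] = activities[tf_row[g]]
        else:
            drive = np.zeros(cfg.n_cells)
            for s, w in incoming[g]:
                drive += w * activities[tf_row[s]]
            values[i] = _softplus(drive)
        values[i] += np.abs(rng.normal(0.0, cfg.noise_sd, size=cfg.n_cells))
    if cfg.dropout_rate > 0:
        values[rng.random(values.shape) < cfg.dropout_rate] = 0.0
    cells = tuple(f"C{j + 1}" for j in range(cfg.n_cells))
    return ExpressionMatrix(tuple(net.genes), cells, values)


def simulate(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, PriorNetwork]:
    """Plant a network and simulate its expression matrix in one call."""
    net = simulate_grn(cfg)
    return simulate_expression(net, cfg), net


def make_fixture(
    name: str,
    out_dir: str | Path | None = None,
    **overrides,
) -> tuple[ExpressionMatrix, PriorNetwork, dict[str, Path] | None]:
    """Build a named preset fixture, optionally writing the standard files.

    Presets (pinned seeds): ``smoke`` (10 TFs / 50 genes / 100 cells /
    density 0.05), ``strong_signal`` (25 / 200 / 300 / 0.05, noise 0.1,
    dropout 0.2) and ``dense`` (15 / 100 / 200 / 0.4).  ``overrides`` may
    replace any :class:`SyntheticConfig` field (e.g. ``noise_sd`` or
    ``seed`` for perturbation studies).  When ``out_dir`` is given, writes
    ``ExpressionData.csv``, ``refNetwork.csv`` and ``TFs.txt`` and returns
    their paths.
    """
    if name not in PRESETS:
        raise ReglinkError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], **overrides)
    x, net = simulate(cfg)
    paths = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "ExpressionData.csv",
            "network": out / "refNetwork.csv",
            "tfs": out / "TFs.txt",
        }
        write_expression(x, paths["expression"])
        write_network(net, paths["network"])
        paths["tfs"].write_text("\n".join(sorted(net.tf_set)) + "\n")
    return x, net, paths
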