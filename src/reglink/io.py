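"""Readers and writers for the flat-file dialects used in GRN benchmarking.

Three inputs are supported, matching the layout popularised by the BEELINE
benchmark suite:

* an expression matrix CSV/TSV with genes as rows (first column gene IDs,
  header row cell IDs);
* a two-column directed edge list ``source,target`` describing known
  TF -> target regulations (header optional);
* a plain-text TF list, one identifier per line.

The single output format is a ranked candidate-edge CSV with the header
``Gene1,Gene2,EdgeWeight`` sorted by descending score.

Gene identifiers are matched by exact, case-sensitive string equality
throughout; readers accept ``case_insensitive=True`` to upper-case all
identifiers at the boundary instead.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ReglinkError

logger = logging.getLogger(__name__)

#: header tokens recognised (case-insensitively) as an edge-list header row
_NETWORK_HEADER_TOKENS = {"gene1", "gene2", "source", "target", "tf", "regulator", "gene"}


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene x cell nonnegative expression matrix with identifiers.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in cell
    ``cell_ids[j]``.  Raw counts/TPM before preprocessing, log-units after.
    """

    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        n, m = len(self.gene_ids), len(self.cell_ids)
        if n < 1 or m < 1:
            raise ReglinkError("expression matrix must have at least one gene and one cell")
        if values.shape != (n, m):
            raise ReglinkError(
                f"value shape {values.shape} does not match {n} genes x {m} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(values)):
            raise ReglinkError("expression values must be finite")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ReglinkError(
                f"negative expression value {values[i, j]} for gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Return the matrix restricted to ``keep``, in the order given."""
        index = self.gene_index()
        missing = [g for g in keep if g not in index]
        if missing:
            raise ReglinkError(f"unknown gene identifiers: {missing[:5]}")
        rows = [index[g] for g in keep]
        return ExpressionMatrix(tuple(keep), self.cell_ids, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


@dataclass(frozen=True)
class PriorNetwork:
    """A directed prior regulatory network over an ordered gene universe.

    Edges run TF -> target; ``tf_set`` names the genes allowed as edge
    sources (and as sources of sampled negatives).
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    tf_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_unique(self.genes, "gene")
        gene_set = set(self.genes)
        tf_set = frozenset(self.tf_set) or frozenset(s for s, _ in self.edges)
        object.__setattr__(self, "tf_set", tf_set)
        object.__setattr__(self, "edges", frozenset(self.edges))
        if not tf_set <= gene_set:
            raise ReglinkError("tf_set contains identifiers outside the gene universe")
        for s, t in self.edges:
            if s == t:
                raise ReglinkError(f"self-edge ({s},{t}) not allowed in a prior network")
            if s not in gene_set or t not in gene_set:
                raise ReglinkError(f"edge ({s},{t}) has an endpoint outside the gene universe")
            if s not in tf_set:
                raise ReglinkError(f"edge source {s!r} is not in the TF set")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def density(self) -> float:
        """Fraction of possible TF -> gene pairs that are edges."""
        possible = len(self.tf_set) * (len(self.genes) - 1)
        if possible == 0:
            raise ReglinkError("network density undefined: no candidate TF->gene pairs")
        return len(self.edges) / possible

    def restrict(self, keep: Sequence[str]) -> "PriorNetwork":
        """Restrict the network to genes in ``keep`` (order taken from ``keep``)."""
        keep_set = set(keep)
        edges = frozenset((s, t) for s, t in self.edges if s in keep_set and t in keep_set)
        return PriorNetwork(tuple(keep), edges, frozenset(self.tf_set & keep_set))


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ReglinkError(f"duplicate {kind} identifier {x!r}")
        seen.add(x)


def _maybe_upper(ids: Iterable[str], case_insensitive: bool) -> list[str]:
    return [x.upper() for x in ids] if case_insensitive else list(ids)


def read_expression(path: str | Path, case_insensitive: bool = False) -> ExpressionMatrix:
    """Read a genes-as-rows expression CSV/TSV into an :class:`ExpressionMatrix`.

    The first column holds gene IDs and the header row holds cell IDs; the
    delimiter is auto-detected from comma/tab.  Row and column order are
    preserved.  Duplicate gene IDs, non-numeric cells and negative values
    are hard errors that name the offending location.
    """
    path = Path(path)
    if not path.exists():
        raise ReglinkError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    gene_ids = _maybe_upper((str(g) for g in df.index), case_insensitive)
    cell_ids = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
    if len(bad):
        i, j = bad[0]
        raise ReglinkError(
            f"non-numeric expression value {df.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, cell {cell_ids[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ReglinkError(f"missing expression value at gene {gene_ids[i]!r}, cell {cell_ids[j]!r}")
    # parse through Python float(): correctly rounded, so write/read round
    # trips are exact to the last ULP (pandas' fast parser is not)
    values = np.array([[float(v) for v in row] for row in df.itertuples(index=False)])
    return ExpressionMatrix(tuple(gene_ids), tuple(cell_ids), values)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the genes-as-rows CSV dialect."""
    # %.17g round-trips IEEE doubles exactly
    x.to_frame().to_csv(Path(path), index_label="Gene", float_format="%.17g")


def read_tf_list(path: str | Path, case_insensitive: bool = False) -> list[str]:
    """Read a one-identifier-per-line TF list, de-duplicated, order preserved."""
    path = Path(path)
    if not path.exists():
        raise ReglinkError(f"TF list file not found: {path}")
    out: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        token = line.strip()
        if case_insensitive:
            token = token.upper()
        if token and token not in seen:
            out.append(token)
            seen.add(token)
    return out


def read_network(
    path: str | Path,
    gene_universe: Sequence[str] | None = None,
    tf_list: Sequence[str] | None = None,
    case_insensitive: bool = False,
) -> PriorNetwork:
    """Read a two-column ``source,target`` edge list into a :class:`PriorNetwork`.

    A header row is auto-detected (recognised header tokens, or — when a
    gene universe is supplied — a first row whose entries fall outside it).
    Edges are de-duplicated; self-edges are dropped (the encoder adds its
    own self-loops); when ``gene_universe`` is given, edges with endpoints
    outside it are dropped.  Dropped counts are logged.  An empty edge set
    after filtering is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise ReglinkError(f"network file not found: {path}")
    rows: list[tuple[str, str]] = []
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    for rec in csv.reader(text.splitlines(), delimiter=delimiter):
        if not rec or all(not c.strip() for c in rec):
            continue
        if len(rec) < 2:
            raise ReglinkError(f"network row {rec!r} in {path} has fewer than two columns")
        rows.append((rec[0].strip(), rec[1].strip()))
    if not rows:
        raise ReglinkError(f"network file {path} is empty")

    universe = _maybe_upper(gene_universe, case_insensitive) if gene_universe is not None else None
    first = rows[0]
    is_header = {first[0].lower(), first[1].lower()} <= _NETWORK_HEADER_TOKENS
    if not is_header and universe is not None:
        uni = set(universe)
        is_header = first[0] not in uni and first[1] not in uni and len(rows) > 1
    if is_header:
        rows = rows[1:]
    if case_insensitive:
        rows = [(s.upper(), t.upper()) for s, t in rows]

    n_raw = len(rows)
    edges = {pair for pair in rows}
    n_self = sum(1 for s, t in edges if s == t)
    edges = {(s, t) for s, t in edges if s != t}
    if n_self:
        logger.info("read_network: dropped %d self-edge(s) from %s", n_self, path)
    if universe is not None:
        uni = set(universe)
        n_before = len(edges)
        edges = {(s, t) for s, t in edges if s in uni and t in uni}
        if n_before - len(edges):
            logger.info(
                "read_network: dropped %d edge(s) outside the %d-gene universe",
                n_before - len(edges), len(uni),
            )
    if not edges:
        raise ReglinkError(f"no edges remain after filtering {path} ({n_raw} rows read)")

    tfs = _maybe_upper(tf_list, case_insensitive) if tf_list is not None else None
    if tfs is not None:
        tf_set = frozenset(tfs)
        n_before = len(edges)
        edges = {(s, t) for s, t in edges if s in tf_set}
        if n_before - len(edges):
            logger.info(
                "read_network: dropped %d edge(s) whose source is not a listed TF",
                n_before - len(edges),
            )
        if not edges:
            raise ReglinkError(f"no edges remain after TF-source filtering of {path}")
    if universe is not None:
        genes = tuple(universe)
    else:
        genes = tuple(sorted({g for e in edges for g in e} | (set(tfs) if tfs else set())))
    tf_set = frozenset(tfs) & set(genes) if tfs is not None else frozenset(s for s, _ in edges)
    return PriorNetwork(genes, frozenset(edges), tf_set)


def write_network(net: PriorNetwork, path: str | Path) -> None:
    """Write the edge list as ``Gene1,Gene2`` CSV (sorted, reproducible)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Gene1", "Gene2"])
        for s, t in sorted(net.edges):
            w.writerow([s, t])


def write_ranked_edges(
    pairs: Sequence[tuple[str, str, float]], path: str | Path
) -> None:
    """Write scored candidate edges as ``Gene1,Gene2,EdgeWeight`` CSV.

    Rows are sorted by score descending; ties are broken by (source,
    target) lexicographic order so output is deterministic.
    """
    for s, t, score in pairs:
        if not math.isfinite(score) or score < 0:
            raise ReglinkError(f"score for edge ({s},{t}) must be finite and >= 0, got {score}")
    ordered = sorted(pairs, key=lambda p: (-p[2], p[0], p[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Gene1", "Gene2", "EdgeWeight"])
        for s, t, score in ordered:
            w.writerow([s, t, repr(float(score))])


def read_ranked_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read back a ranked-edge CSV written by :func:`write_ranked_edges`."""
    df = pd.read_csv(Path(path))
    return [(str(a), str(b), float(c)) for a, b, c in df.itertuples(index=False)]
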