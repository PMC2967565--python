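"""Core data types and I/O for expression matrices and regulatory networks.

File dialects
-------------
Expression matrices are tab-separated text (UTF-8): a header row of time
labels, one row per gene with the gene id in the first column.  Labels may
not contain the delimiter (writers raise instead of quoting).

Networks are written either as a two-column TSV edge list with a
``regulator<TAB>target`` header (preceded by a ``# genes:`` comment line
recording the full gene universe, so isolated genes survive a round trip)
or as SIF lines ``regulator<TAB>regulates<TAB>target`` (SIF carries no
universe; isolated genes are lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "DegenerateDiscretizationWarning",
    "ExpressionMatrix",
    "DiscreteMatrix",
    "RegulatoryNetwork",
    "ConfusionCounts",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
]


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending location."""


class DegenerateDiscretizationWarning(UserWarning):
    """A row/column had too few distinct values for the requested intervals."""


def _check_labels(labels: Sequence[str], what: str, delimiter: str = "\t") -> Tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    for lab in labels:
        if delimiter in lab or "\n" in lab:
            raise ValidationError(f"{what} label {lab!r} contains the delimiter")
    return labels


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes x time-points matrix with row/column labels.

    Parameters
    ----------
    values : (N, M) float array, no missing values, N >= 2, M >= 2.
    gene_ids : N unique row labels.
    time_labels : M column labels in temporal order.
    """

    values: np.ndarray
    gene_ids: Tuple[str, ...]
    time_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _check_labels(self.gene_ids, "gene"))
        object.__setattr__(self, "time_labels", _check_labels(self.time_labels, "time"))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, m = values.shape
        if n < 2 or m < 2:
            raise ValidationError(f"matrix must be at least 2x2, got {n}x{m}")
        if len(self.gene_ids) != n:
            raise ValidationError("gene_ids length does not match row count")
        if len(self.time_labels) != m:
            raise ValidationError("time_labels length does not match column count")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {', '.join(dupes)}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class DiscreteMatrix:
    """Integer level matrix (values in 1..k) produced by a discretizer."""

    levels: np.ndarray
    k: int
    method_tag: str
    gene_ids: Tuple[str, ...]
    time_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        if self.k < 2:
            raise ValidationError("interval count k must be >= 2")
        if levels.ndim != 2:
            raise ValidationError("levels must be a 2-D matrix")
        if levels.shape != (len(self.gene_ids), len(self.time_labels)):
            raise ValidationError("levels shape does not match labels")
        if levels.min() < 1 or levels.max() > self.k:
            raise ValidationError(f"levels must lie in 1..{self.k}")


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed regulator->target edge set over a gene universe.

    ``genes`` preserves the caller's ordering (used for deterministic
    iteration); ``edges`` is a frozenset of (regulator, target) pairs.
    """

    genes: Tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset((str(a), str(b)) for a, b in self.edges))
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene ids in network universe")
        universe = set(genes)
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r}")
            if a not in universe or b not in universe:
                raise ValidationError(f"edge ({a!r}, {b!r}) endpoint outside gene universe")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list:
        return sorted(self.edges)

    def undirected_pairs(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.edges)


@dataclass(frozen=True)
class ConfusionCounts:
    """Tp/Tn/Fp/Fn for one inferred-vs-true network comparison.

    ``sn``/``sp`` are ``None`` when their denominator is zero (no true
    edges / no true non-edges); ``ta`` is always defined for a non-empty
    pair universe.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sn(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def sp(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d > 0 else None

    @property
    def ta(self) -> Optional[float]:
        return (self.tp + self.tn) / self.total if self.total > 0 else None


# ---------------------------------------------------------------------------
# Expression matrix I/O


def read_expression(path, delimiter: str = "\t", impute_missing: bool = False) -> ExpressionMatrix:
    """Load an expression matrix from delimited text.

    First row holds time labels, first column gene ids.  Missing values are
    rejected unless ``impute_missing`` is set, in which case they are filled
    by linear interpolation along the time axis (edge gaps extended).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"time {df.columns[c]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at gene {df.index[r]!r}, time {df.columns[c]!r}; "
                "pass impute_missing=True to interpolate"
            )
        values = (
            pd.DataFrame(values)
            .interpolate(axis=1, limit_direction="both")
            .to_numpy()
        )
    return ExpressionMatrix(values, tuple(df.index), tuple(df.columns))


def write_expression(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write ``m`` as delimited text round-trippable by :func:`read_expression`."""
    if not isinstance(m, ExpressionMatrix):
        raise ValidationError("write_expression expects an ExpressionMatrix")
    _check_labels(m.gene_ids, "gene", delimiter)
    _check_labels(m.time_labels, "time", delimiter)
    df = pd.DataFrame(m.values, index=list(m.gene_ids), columns=list(m.time_labels))
    df.to_csv(Path(path), sep=delimiter, index_label="gene")


def write_discrete(d: DiscreteMatrix, path, delimiter: str = "\t") -> None:
    """Write integer levels with the same layout as an expression matrix."""
    df = pd.DataFrame(d.levels, index=list(d.gene_ids), columns=list(d.time_labels))
    df.to_csv(Path(path), sep=delimiter, index_label="gene")


def read_discrete(path, k: int, method_tag: str = "file", delimiter: str = "\t") -> DiscreteMatrix:
    """Load a previously written level matrix; ``k`` must be supplied."""
    em = read_expression(path, delimiter=delimiter)
    levels = em.values
    if not np.allclose(levels, np.round(levels)):
        raise ParseError(f"{path} contains non-integer levels")
    return DiscreteMatrix(levels.astype(int), k, method_tag, em.gene_ids, em.time_labels)


# ---------------------------------------------------------------------------
# Network I/O

_GENES_COMMENT = "# genes:"
_TSV_HEADER = "regulator\ttarget"


def read_network(path) -> RegulatoryNetwork:
    """Load a directed network from a 2-column TSV edge list or a SIF file.

    Duplicated edges are collapsed; a self-loop or malformed line raises
    with its line number.
    """
    path = Path(path)
    edges = set()
    genes_from_comment: Optional[Tuple[str, ...]] = None
    endpoint_order: list = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_GENES_COMMENT):
                genes_from_comment = tuple(line[len(_GENES_COMMENT):].strip().split("\t"))
                continue
            if line.startswith("#"):
                continue
            if line == _TSV_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _interaction, b = fields
            else:
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty gene id")
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
            for g in (a, b):
                if g not in endpoint_order:
                    endpoint_order.append(g)
            edges.add((a, b))
    genes = genes_from_comment if genes_from_comment is not None else tuple(endpoint_order)
    return RegulatoryNetwork(genes, frozenset(edges))


def write_network(n: RegulatoryNetwork, path, format: Literal["tsv", "sif"] = "tsv") -> None:
    """Write ``n`` with deterministic (lexicographic) edge ordering."""
    if format not in ("tsv", "sif"):
        raise ValidationError(f"unknown network format {format!r}")
    lines = []
    if format == "tsv":
        lines.append(_GENES_COMMENT + " " + "\t".join(n.genes))
        lines.append(_TSV_HEADER)
        lines.extend(f"{a}\t{b}" for a, b in n.sorted_edges())
    else:
        lines.extend(f"{a}\tregulates\t{b}" for a, b in n.sorted_edges())
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
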