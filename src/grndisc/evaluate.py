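"""Confusion counts and Sn/Sp/TA for inferred-vs-true network comparison."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

from .core import ConfusionCounts, RegulatoryNetwork, ValidationError, read_network

__all__ = ["confusion", "evaluate_run"]


def confusion(
    inferred: RegulatoryNetwork,
    truth: RegulatoryNetwork,
    mode: Literal["directed", "undirected"] = "directed",
) -> ConfusionCounts:
    """Tp/Tn/Fp/Fn over the gene-pair universe.

    In ``directed`` mode the universe is all N(N-1) ordered pairs; in
    ``undirected`` mode both networks are collapsed to unordered pairs over
    a universe of N(N-1)/2.  Sensitivity is Tp/(Tp+Fn), specificity
    Tn/(Tn+Fp) and total accuracy (Tp+Tn)/(all pairs); Sn/Sp are ``None``
    when their denominator is empty.
    """
    if mode not in ("directed", "undirected"):
        raise ValidationError(f"unknown mode {mode!r}")
    if set(inferred.genes) != set(truth.genes):
        raise ValidationError("inferred and truth networks have different gene universes")
    n = len(truth.genes)
    if mode == "directed":
        universe = n * (n - 1)
        inf_edges, true_edges = set(inferred.edges), set(truth.edges)
    else:
        universe = n * (n - 1) // 2
        inf_edges = set(inferred.undirected_pairs())
        true_edges = set(truth.undirected_pairs())
    tp = len(inf_edges & true_edges)
    fp = len(inf_edges - true_edges)
    fn = len(true_edges - inf_edges)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.6f}"


def evaluate_run(
    inferred_path,
    truth_path,
    mode: Literal["directed", "undirected"] = "directed",
    out_path=None,
    genes: Optional[Sequence[str]] = None,
) -> ConfusionCounts:
    """File-level wrapper of :func:`confusion` with an optional TSV report.

    ``genes`` overrides the gene universe of both networks (useful when the
    edge-list files omit isolated genes).
    """
    inferred = read_network(inferred_path)
    truth = read_network(truth_path)
    if genes is not None:
        genes = tuple(genes)
        inferred = RegulatoryNetwork(genes, inferred.edges)
        truth = RegulatoryNetwork(genes, truth.edges)
    counts = confusion(inferred, truth, mode)
    if out_path is not None:
        header = "tp\ttn\tfp\tfn\tsn\tsp\tta\tmode"
        line = (
            f"{counts.tp}\t{counts.tn}\t{counts.fp}\t{counts.fn}\t"
            f"{_fmt(counts.sn)}\t{_fmt(counts.sp)}\t{_fmt(counts.ta)}\t{mode}"
        )
        Path(out_path).write_text(header + "\n" + line + "\n", encoding="utf-8")
    return counts
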