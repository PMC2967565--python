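"""Network inference from discretized time-course data.

Three algorithms share the discrete genes x time-points matrix, with each
time point treated as one i.i.d. joint observation of all genes (static
Bayesian-network view):

* :func:`k2` — classic greedy parent selection under a total node order,
  scored by the Cooper-Herskovits marginal likelihood (log space).  The
  order comes from :func:`node_order`, which ranks genes by the time point
  of their first expression change (>= ``up_cut``-fold up or <= ``down_cut``
  -fold down relative to the first time point).
* :func:`greedy_search` — first-ascent hill climbing over DAGs with
  add/delete/reverse moves and a decomposable score (BIC by default).
* :func:`aracne` — pairwise mutual information, chi-square significance
  thresholding, then Data Processing Inequality pruning of triangles; its
  undirected result is expanded to both ordered pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .core import DiscreteMatrix, ExpressionMatrix, RegulatoryNetwork, ValidationError

__all__ = [
    "NodeOrder",
    "MIMatrix",
    "node_order",
    "k2",
    "greedy_search",
    "mutual_information",
    "aracne",
]


# ---------------------------------------------------------------------------
# Node ordering by time of initial change


@dataclass(frozen=True)
class NodeOrder:
    """Genes sorted by first-change time point, earliest changers first.

    ``change_times`` maps gene id to the 1-based time point of its first
    up-/down-regulation, or ``None`` if its profile never crosses either
    cutoff.  Genes earlier in ``genes`` are eligible parents of later genes.
    """

    genes: Tuple[str, ...]
    change_times: Dict[str, Optional[int]]

    def __post_init__(self) -> None:
        if set(self.genes) != set(self.change_times):
            raise ValidationError("change_times keys must equal the ordered genes")
        times = [self.change_times[g] for g in self.genes]
        finite = [t for t in times if t is not None]
        if any(a > b for a, b in zip(finite, finite[1:])):
            raise ValidationError("change times must be non-decreasing along the order")
        if None in times:
            first_none = times.index(None)
            if any(t is not None for t in times[first_none:]):
                raise ValidationError("genes without a change time must come last")


def node_order(m: ExpressionMatrix, up_cut: float = 1.2, down_cut: float = 0.7) -> NodeOrder:
    """Order genes by the time point of their initial expression change.

    The baseline is each gene's first time point.  The initial change is the
    earliest time point ``t >= 2`` whose ratio to baseline is ``>= up_cut``
    (up-regulation) or ``<= down_cut`` (down-regulation).  Genes are sorted
    ascending by change time, never-changing genes last, ties broken by
    input row order.
    """
    baseline = m.values[:, 0]
    zeros = np.flatnonzero(baseline == 0)
    if zeros.size:
        raise ValidationError(f"gene {m.gene_ids[zeros[0]]!r} has zero baseline expression")
    ratio = m.values / baseline[:, None]
    changed = (ratio[:, 1:] >= up_cut) | (ratio[:, 1:] <= down_cut)
    change_times: Dict[str, Optional[int]] = {}
    for i, gid in enumerate(m.gene_ids):
        hits = np.flatnonzero(changed[i])
        change_times[gid] = int(hits[0]) + 2 if hits.size else None  # 1-based time point
    order = sorted(
        range(m.n_genes),
        key=lambda i: (
            change_times[m.gene_ids[i]] is None,
            change_times[m.gene_ids[i]] if change_times[m.gene_ids[i]] is not None else 0,
            i,
        ),
    )
    return NodeOrder(tuple(m.gene_ids[i] for i in order), change_times)


# ---------------------------------------------------------------------------
# Family scores (columns of the discrete matrix = samples)


def _family_counts(child: np.ndarray, parents: List[np.ndarray], r: int) -> np.ndarray:
    """Counts N[j, c] over observed parent configurations j and child states c.

    Levels are 1-based; parent configurations are mixed-radix encoded.
    """
    m = child.size
    if parents:
        code = np.zeros(m, dtype=np.int64)
        for p in parents:
            code = code * r + (p - 1)
        configs, inv = np.unique(code, return_inverse=True)
        flat = inv * r + (child - 1)
        counts = np.bincount(flat, minlength=configs.size * r)
        return counts.reshape(configs.size, r)
    return np.bincount(child - 1, minlength=r).reshape(1, r)


def _ch_family_score(child: np.ndarray, parents: List[np.ndarray], r: int) -> float:
    """Cooper-Herskovits log marginal likelihood of one family (uniform prior)."""
    counts = _family_counts(child, parents, r)
    nj = counts.sum(axis=1)
    return float(
        np.sum(gammaln(r) - gammaln(nj + r)) + np.sum(gammaln(counts + 1))
    )


def _bic_family_score(child: np.ndarray, parents: List[np.ndarray], r: int) -> float:
    """BIC family score: multinomial log likelihood minus parameter penalty."""
    counts = _family_counts(child, parents, r)
    nj = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * (np.log(counts) - np.log(nj)), 0.0).sum()
    m = child.size
    n_params = (r ** len(parents)) * (r - 1)
    return float(ll - 0.5 * math.log(m) * n_params)


_FAMILY_SCORES = {"k2_marginal": _ch_family_score, "bic": _bic_family_score}


# ---------------------------------------------------------------------------
# K2


def k2(d: DiscreteMatrix, order: NodeOrder, max_parents: int = 3) -> RegulatoryNetwork:
    """K2 structure search: greedy parent addition under a fixed node order.

    For each gene, candidate parents are the genes preceding it in
    ``order``; the candidate whose addition most increases the family's
    Cooper-Herskovits score is added until no addition improves the score or
    ``max_parents`` is reached.  Ties keep the earliest candidate in order.
    """
    if set(order.genes) != set(d.gene_ids):
        missing = sorted(set(d.gene_ids) - set(order.genes))
        raise ValidationError(f"node order does not cover genes: {missing}")
    if max_parents < 0:
        raise ValidationError("max_parents must be >= 0")
    row = {gid: d.levels[i] for i, gid in enumerate(d.gene_ids)}
    edges: Set[Tuple[str, str]] = set()
    for pos, gid in enumerate(order.genes):
        child = row[gid]
        candidates = list(order.genes[:pos])
        parents: List[str] = []
        score = _ch_family_score(child, [], d.k)
        while len(parents) < max_parents and len(parents) < len(candidates):
            best_gain, best = 0.0, None
            for cand in candidates:
                if cand in parents:
                    continue
                s = _ch_family_score(child, [row[p] for p in parents + [cand]], d.k)
                if s - score > best_gain + 1e-12:
                    best_gain, best = s - score, cand
            if best is None:
                break
            parents.append(best)
            score += best_gain
        edges.update((p, gid) for p in parents)
    return RegulatoryNetwork(d.gene_ids, frozenset(edges))


# ---------------------------------------------------------------------------
# Greedy hill climbing over DAGs


def _creates_cycle(parents: Dict[int, Set[int]], src: int, dst: int) -> bool:
    """True if adding src->dst would close a directed cycle (src reachable from dst)."""
    children: Dict[int, List[int]] = {}
    for node, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(node)
    # walk forward from dst looking for src
    stack, seen = [dst], {dst}
    while stack:
        node = stack.pop()
        if node == src:
            return True
        for nxt in children.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def greedy_search(
    d: DiscreteMatrix,
    score: str = "bic",
    max_parents: int = 3,
    seed: Optional[int] = None,
) -> RegulatoryNetwork:
    """First-ascent hill climbing over DAGs from the empty graph.

    Moves are enumerated deterministically — for each ordered gene-index
    pair (i, j), i != j in row order: add i->j, delete i->j, reverse i->j —
    and the first score-improving legal move is applied; the search stops at
    a local optimum.  ``seed`` is unused (the procedure is deterministic)
    and kept for API uniformity.
    """
    if score not in _FAMILY_SCORES:
        raise ValidationError(f"unknown score {score!r}; choose from {sorted(_FAMILY_SCORES)}")
    fam = _FAMILY_SCORES[score]
    n = len(d.gene_ids)
    rows = d.levels
    parents: Dict[int, Set[int]] = {i: set() for i in range(n)}
    fscore = {i: fam(rows[i], [], d.k) for i in range(n)}

    def family(i: int, ps: Set[int]) -> float:
        return fam(rows[i], [rows[p] for p in sorted(ps)], d.k)

    improved = True
    while improved:
        improved = False
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if i not in parents[j]:
                    # add i -> j
                    if len(parents[j]) >= max_parents or _creates_cycle(parents, i, j):
                        continue
                    new = family(j, parents[j] | {i})
                    if new - fscore[j] > 1e-9:
                        parents[j].add(i)
                        fscore[j] = new
                        improved = True
                        break
                else:
                    # delete i -> j
                    new = family(j, parents[j] - {i})
                    if new - fscore[j] > 1e-9:
                        parents[j].remove(i)
                        fscore[j] = new
                        improved = True
                        break
                    # reverse i -> j  (becomes j -> i)
                    if len(parents[i]) >= max_parents:
                        continue
                    parents[j].remove(i)
                    if _creates_cycle(parents, j, i):
                        parents[j].add(i)
                        continue
                    new_j = family(j, parents[j])
                    new_i = family(i, parents[i] | {j})
                    if (new_j + new_i) - (fscore[j] + fscore[i]) > 1e-9:
                        parents[i].add(j)
                        fscore[j], fscore[i] = new_j, new_i
                        improved = True
                        break
                    parents[j].add(i)
            if improved:
                break
    edges = frozenset(
        (d.gene_ids[p], d.gene_ids[i]) for i, ps in parents.items() for p in ps
    )
    return RegulatoryNetwork(d.gene_ids, edges)


# ---------------------------------------------------------------------------
# Mutual information and ARACNE


@dataclass(frozen=True)
class MIMatrix:
    """Pairwise plug-in mutual information (nats) with chi-square p-values."""

    mi: np.ndarray
    pvalues: np.ndarray
    gene_ids: Tuple[str, ...]

    def pair(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.mi[i, j])


def _pair_mi(x: np.ndarray, y: np.ndarray, k: int) -> Tuple[float, float]:
    m = x.size
    joint = np.bincount((x - 1) * k + (y - 1), minlength=k * k).reshape(k, k)
    joint = joint[joint.sum(axis=1) > 0][:, joint.sum(axis=0) > 0]
    r, c = joint.shape
    if r < 2 or c < 2:
        return 0.0, 1.0
    p = joint / m
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    mi = max(float(terms.sum()), 0.0)
    # large-sample null: 2*M*MI ~ chi2 with (r-1)(c-1) d.f.
    pval = float(chi2.sf(2.0 * m * mi, (r - 1) * (c - 1)))
    return mi, pval


def mutual_information(d: DiscreteMatrix) -> MIMatrix:
    """Plug-in MI (natural log) for every gene pair across time points.

    Degrees of freedom for the chi-square p-value use the *observed* level
    counts per gene; a gene with a single observed level yields MI 0, p 1.
    """
    n = len(d.gene_ids)
    mi = np.zeros((n, n))
    pv = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m_ij, p_ij = _pair_mi(d.levels[i], d.levels[j], d.k)
            mi[i, j] = mi[j, i] = m_ij
            pv[i, j] = pv[j, i] = p_ij
    return MIMatrix(mi, pv, d.gene_ids)


def aracne(
    d: DiscreteMatrix,
    p_threshold: float = 1e-7,
    dpi_tolerance: float = 0.15,
) -> RegulatoryNetwork:
    """MI thresholding plus Data Processing Inequality pruning.

    Pairs with MI p-value <= ``p_threshold`` are kept; then every triangle
    of kept edges is scanned in lexicographic gene-index order and an edge
    (a, c) is marked for removal when
    ``MI(a,c) < min(MI(a,b), MI(b,c)) * (1 - dpi_tolerance)``.  Removals
    are applied only after the full scan.  The undirected result is
    expanded to both ordered pairs.
    """
    if not 0 <= dpi_tolerance <= 1:
        raise ValidationError("dpi_tolerance must be in [0, 1]")
    mim = mutual_information(d)
    n = len(d.gene_ids)
    kept: Set[FrozenSet[int]] = {
        frozenset((i, j))
        for i in range(n)
        for j in range(i + 1, n)
        if mim.pvalues[i, j] <= p_threshold
    }
    slack = 1.0 - dpi_tolerance
    to_remove: Set[FrozenSet[int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) not in kept:
                continue
            for l in range(j + 1, n):
                e_jl, e_il = frozenset((j, l)), frozenset((i, l))
                if e_jl not in kept or e_il not in kept:
                    continue
                m_ij, m_jl, m_il = mim.mi[i, j], mim.mi[j, l], mim.mi[i, l]
                if m_ij < min(m_jl, m_il) * slack:
                    to_remove.add(frozenset((i, j)))
                if m_jl < min(m_ij, m_il) * slack:
                    to_remove.add(e_jl)
                if m_il < min(m_ij, m_jl) * slack:
                    to_remove.add(e_il)
    kept -= to_remove
    edges = set()
    for pair in kept:
        i, j = sorted(pair)
        edges.add((d.gene_ids[i], d.gene_ids[j]))
        edges.add((d.gene_ids[j], d.gene_ids[i]))
    return RegulatoryNetwork(d.gene_ids, frozenset(edges))
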