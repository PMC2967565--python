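"""Synthetic benchmark data: ground-truth directed networks plus time-course
expression matrices with lagged regulator->target signal and Gaussian noise.

The generative model is a parametric surrogate for resampled-microarray
generators: each dataset pairs an acyclic directed network with a positive
genes x time-points matrix in which source genes follow smoothed random
walks and each target tracks a saturating function of its regulators at a
fixed lag.  Latent trajectories live on a log scale and are exponentiated
around ``baseline``, so every value is strictly positive and fold changes
relative to the first time point are well defined.

Determinism: all randomness flows from ``SimConfig.seed`` through
``numpy.random.SeedSequence``; dataset ``i`` of a suite uses the ``i``-th
spawned child sequence, so any single dataset can be regenerated bit-exactly
without generating the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import networkx as nx

from .core import (
    ExpressionMatrix,
    RegulatoryNetwork,
    ValidationError,
    write_expression,
    write_network,
)

__all__ = [
    "SimConfig",
    "simulate_network",
    "simulate_expression",
    "simulate_dataset",
    "simulate_suite",
    "generate_benchmark_suite",
]




@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic benchmark generator."""

    n_genes: int = 50
    n_timepoints: int = 25
    n_datasets: int = 100
    n_edges: int = 60
    regulator_fraction: float = 0.3
    lag: int = 1
    effect_size: float = 1.0
    source_amplitude: float = 0.5
    noise_sd: float = 0.1
    baseline: float = 100.0
    baseline_log_sd: float = 1.0
    seed: int = 0
    allow_cycles: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints must be >= 3")
        if self.n_datasets < 1:
            raise ValidationError("n_datasets must be >= 1")
        if self.n_edges < 1:
            raise ValidationError("n_edges must be >= 1")
        if not 0 < self.regulator_fraction <= 1:
            raise ValidationError("regulator_fraction must be in (0, 1]")
        if self.lag < 1 or self.lag >= self.n_timepoints:
            raise ValidationError("lag must be in [1, n_timepoints)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.baseline <= 0:
            raise ValidationError("baseline must be > 0")
        if self.baseline_log_sd < 0:
            raise ValidationError("baseline_log_sd must be >= 0")
        if self.source_amplitude <= 0:
            raise ValidationError("source_amplitude must be > 0")

    def gene_ids(self) -> Tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))

    def time_labels(self) -> Tuple[str, ...]:
        return tuple(f"T{t + 1}" for t in range(self.n_timepoints))


def simulate_network(cfg: SimConfig, rng: np.random.Generator) -> RegulatoryNetwork:
    """Sample an acyclic directed network.

    A random permutation of the genes serves as topological order; the first
    ``ceil(regulator_fraction * n)`` genes of that order form the regulator
    pool.  Edges run from a regulator to any strictly later gene, sampled
    without replacement with probability proportional to a heavy-tailed
    (Pareto) per-regulator weight, giving hub-like out-degrees.
    """
    genes = cfg.gene_ids()
    n = cfg.n_genes
    order = rng.permutation(n)
    n_reg = max(1, int(np.ceil(cfg.regulator_fraction * n)))
    reg_weights = 1.0 + rng.pareto(1.5, size=n_reg)
    candidates: List[Tuple[int, int]] = []
    weights: List[float] = []
    for pos in range(n_reg):
        for tgt_pos in range(pos + 1, n):
            candidates.append((order[pos], order[tgt_pos]))
            weights.append(reg_weights[pos])
    if cfg.n_edges > len(candidates):
        raise ValidationError(
            f"requested {cfg.n_edges} edges but only {len(candidates)} "
            "regulator->target pairs are available"
        )
    w = np.asarray(weights)
    idx = rng.choice(len(candidates), size=cfg.n_edges, replace=False, p=w / w.sum())
    edges = frozenset((genes[candidates[i][0]], genes[candidates[i][1]]) for i in idx)
    return RegulatoryNetwork(genes, edges)


def _smooth_walk(rng: np.random.Generator, m: int) -> np.ndarray:
    """Zero-start smoothed random walk with roughly unit scale."""
    steps = rng.normal(0.0, 1.0, size=m)
    z = np.cumsum(steps)
    kernel = np.ones(3) / 3.0
    z = np.convolve(np.pad(z, 1, mode="edge"), kernel, mode="valid")
    z -= z[0]
    scale = max(np.abs(z).max(), 1e-9)
    return z / scale * np.sqrt(m) / 3.0


def simulate_expression(
    net: RegulatoryNetwork, cfg: SimConfig, rng: np.random.Generator
) -> ExpressionMatrix:
    """Generate a positive expression matrix consistent with ``net``.

    Source genes (no parents) get smoothed random-walk latent trajectories;
    each target's latent value at time ``t`` is
    ``effect_size * tanh(mean of parent latents at t - lag)`` plus
    ``N(0, noise_sd)`` noise.  Expression is ``baseline_g * exp(latent)``
    where each gene's baseline is drawn log-normally around ``baseline``
    with log-scale sd ``baseline_log_sd`` (microarray genes span orders of
    magnitude in absolute level; set it to 0 for homogeneous baselines).
    """
    genes = net.genes
    if len(genes) != cfg.n_genes:
        raise ValidationError("network gene universe does not match cfg.n_genes")
    m = cfg.n_timepoints
    g = nx.DiGraph()
    g.add_nodes_from(genes)
    g.add_edges_from(net.edges)
    try:
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValidationError("expression simulation requires an acyclic network") from exc
    # deterministic iteration: keep the universe order within topological ranks
    rank = {gid: i for i, gid in enumerate(topo)}
    ordered = sorted(genes, key=lambda gid: (rank[gid], genes.index(gid)))
    z = {}
    for gid in ordered:
        parents = sorted(g.predecessors(gid))
        if not parents:
            z[gid] = cfg.source_amplitude * _smooth_walk(rng, m)
        else:
            pz = np.mean([z[p] for p in parents], axis=0)
            lagged = pz[np.maximum(np.arange(m) - cfg.lag, 0)]
            z[gid] = cfg.effect_size * np.tanh(lagged) + rng.normal(0.0, cfg.noise_sd, size=m)
    gene_baselines = cfg.baseline * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=len(genes))
    )
    values = gene_baselines[:, None] * np.exp(np.vstack([z[gid] for gid in genes]))
    return ExpressionMatrix(values, genes, cfg.time_labels())


def _child_rng(cfg: SimConfig, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_datasets)
    return np.random.default_rng(children[index])


def simulate_dataset(cfg: SimConfig, index: int = 0) -> Tuple[ExpressionMatrix, RegulatoryNetwork]:
    """Dataset ``index`` of the suite defined by ``cfg`` (bit-exact)."""
    if not 0 <= index < cfg.n_datasets:
        raise ValidationError(f"dataset index {index} outside 0..{cfg.n_datasets - 1}")
    rng = _child_rng(cfg, index)
    net = simulate_network(cfg, rng)
    em = simulate_expression(net, cfg, rng)
    return em, net


def simulate_suite(cfg: SimConfig) -> List[Tuple[ExpressionMatrix, RegulatoryNetwork]]:
    """All ``cfg.n_datasets`` (expression, truth) pairs, in order."""
    return [simulate_dataset(cfg, i) for i in range(cfg.n_datasets)]


def generate_benchmark_suite(cfg: SimConfig, out_dir) -> Path:
    """Write the full suite to ``out_dir`` with a TSV manifest.

    Returns the manifest path.  The manifest records the master seed and the
    per-dataset file paths; regeneration from the same config is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["dataset_id\texpression_path\tnetwork_path\tmaster_seed\tn_genes\tn_timepoints"]
    width = len(str(cfg.n_datasets))
    for i in range(cfg.n_datasets):
        em, net = simulate_dataset(cfg, i)
        ds = f"ds{i:0{width}d}"
        epath, npath = f"{ds}_expression.tsv", f"{ds}_network.tsv"
        write_expression(em, out_dir / epath)
        write_network(net, out_dir / npath, format="tsv")
        rows.append(
            f"{ds}\t{epath}\t{npath}\t{cfg.seed}\t{cfg.n_genes}\t{cfg.n_timepoints}"
        )
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return manifest
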