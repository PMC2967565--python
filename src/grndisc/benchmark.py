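"""Factorial benchmark (algorithm x discretizer x interval count x dataset),
balanced three-way ANOVA on the resulting accuracies, and Tukey-Kramer
marginal-means comparison.

Factor naming follows the benchmark table convention: S1 = inference
algorithm, S2 = interval count, S3 = discretization method.  The ANOVA
model contains the three main effects and all two-way interactions (no
three-way term); sums of squares use the standard balanced-design
decomposition, so the design must be complete and balanced.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .core import (
    DegenerateDiscretizationWarning,
    ExpressionMatrix,
    RegulatoryNetwork,
    ValidationError,
)
from .discretize import DISCRETIZERS, discretize
from .evaluate import confusion
from .infer import aracne, greedy_search, k2, node_order

__all__ = [
    "ALGORITHMS",
    "run_benchmark",
    "anova3",
    "marginal_means_comparison",
    "summarize",
]

ALGORITHMS = ("k2", "greedy", "aracne")

_FACTOR_COLS = {"S1": "algorithm", "S2": "k", "S3": "discretizer"}


def _infer_one(
    algorithm: str,
    disc,
    em: ExpressionMatrix,
    truth: RegulatoryNetwork,
    max_parents: int,
    aracne_p: float,
    aracne_t: float,
):
    # ARACNE predicts undirected pairs, so it is scored in undirected mode;
    # K2 and greedy produce directed edges and use the ordered-pair universe.
    if algorithm == "k2":
        net = k2(disc, node_order(em), max_parents=max_parents)
        mode = "directed"
    elif algorithm == "greedy":
        net = greedy_search(disc, max_parents=max_parents)
        mode = "directed"
    elif algorithm == "aracne":
        net = aracne(disc, p_threshold=aracne_p, dpi_tolerance=aracne_t)
        mode = "undirected"
    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    return confusion(net, RegulatoryNetwork(em.gene_ids, truth.edges), mode=mode), mode


def run_benchmark(
    suite: Sequence[Tuple[ExpressionMatrix, RegulatoryNetwork]],
    algorithms: Sequence[str] = ALGORITHMS,
    discretizers: Sequence[str] = tuple(DISCRETIZERS),
    ks: Sequence[int] = (2, 3, 4),
    seed: int = 0,
    max_parents: int = 3,
    aracne_p: float = 1e-7,
    aracne_t: float = 0.15,
) -> pd.DataFrame:
    """Run discretize -> infer -> evaluate over the full factorial design.

    Returns a long-format table with one record per (dataset, algorithm,
    discretizer, k).  Failures of a single cell are recorded (``error``
    column, metrics missing) without aborting the sweep.  K2 and greedy are
    evaluated over the directed ordered-pair universe; ARACNE over unordered
    pairs (see the ``mode`` column).
    """
    for name, axis in (("algorithms", algorithms), ("discretizers", discretizers), ("ks", ks)):
        if not axis:
            raise ValidationError(f"empty design axis: {name}")
    unknown = set(discretizers) - set(DISCRETIZERS)
    if unknown:
        raise ValidationError(f"unknown discretizers: {sorted(unknown)}")
    records: List[dict] = []
    for ds_idx, (em, truth) in enumerate(suite):
        for method, k in itertools.product(discretizers, ks):
            warn_msgs: List[str] = []
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", DegenerateDiscretizationWarning)
                    disc = discretize(em, method, k, seed)
                    warn_msgs = [str(w.message) for w in caught]
                disc_err = None
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                disc, disc_err = None, f"{type(exc).__name__}: {exc}"
            for algorithm in algorithms:
                rec = {
                    "dataset_id": ds_idx,
                    "algorithm": algorithm,
                    "k": int(k),
                    "discretizer": method,
                    "tp": np.nan,
                    "tn": np.nan,
                    "fp": np.nan,
                    "fn": np.nan,
                    "sn": np.nan,
                    "sp": np.nan,
                    "ta": np.nan,
                    "mode": None,
                    "n_warnings": len(warn_msgs),
                    "error": disc_err,
                }
                if disc is not None:
                    try:
                        cc, mode = _infer_one(
                            algorithm, disc, em, truth, max_parents, aracne_p, aracne_t
                        )
                        rec.update(
                            mode=mode,
                            tp=cc.tp,
                            tn=cc.tn,
                            fp=cc.fp,
                            fn=cc.fn,
                            sn=np.nan if cc.sn is None else cc.sn,
                            sp=np.nan if cc.sp is None else cc.sp,
                            ta=np.nan if cc.ta is None else cc.ta,
                            error=None,
                        )
                    except Exception as exc:  # noqa: BLE001
                        rec["error"] = f"{type(exc).__name__}: {exc}"
                records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Balanced three-way ANOVA


def _check_balanced(records: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("algorithm", "k", "discretizer", response):
        if col not in records.columns:
            raise ValidationError(f"records table lacks column {col!r}")
    data = records[["algorithm", "k", "discretizer", response]].copy()
    n_missing = data[response].isna().sum()
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} record(s) with missing {response}", UserWarning, stacklevel=3
        )
        data = data.dropna(subset=[response])
    counts = data.groupby(["algorithm", "k", "discretizer"], observed=True).size()
    a = data["algorithm"].nunique()
    b = data["k"].nunique()
    c = data["discretizer"].nunique()
    if len(counts) != a * b * c or counts.nunique() != 1:
        raise ValidationError(
            "unbalanced or incomplete design; balanced ANOVA requires equal cell "
            "counts — use a regression-based analysis for unbalanced data"
        )
    return data


def anova3(records: pd.DataFrame, response: str = "ta") -> pd.DataFrame:
    """Fixed-effects ANOVA with terms S1 + S2 + S3 + S1:S2 + S1:S3 + S2:S3.

    S1 = algorithm, S2 = interval count, S3 = discretizer.  Sums of squares
    come from the balanced-design decomposition (marginal means); F is
    MS(term)/MS(Error) and p from the F distribution.  Returns a table
    indexed by term with columns sum_sq, df, mean_sq, F, p.  With zero
    error variance F and p are reported as missing.
    """
    data = _check_balanced(records, response)
    y = data[response].to_numpy(dtype=float)
    grand = y.mean()
    n_total = y.size
    ss_total = float(((y - grand) ** 2).sum())

    def _means(cols: List[str]) -> pd.Series:
        return data.groupby(cols, observed=True)[response].mean()

    factors = {term: _FACTOR_COLS[term] for term in ("S1", "S2", "S3")}
    levels = {t: data[c].nunique() for t, c in factors.items()}
    reps = n_total // (levels["S1"] * levels["S2"] * levels["S3"])

    main_means = {t: _means([c]) for t, c in factors.items()}
    ss: Dict[str, float] = {}
    df: Dict[str, int] = {}
    for t, c in factors.items():
        weight = n_total / levels[t]
        ss[t] = float(weight * ((main_means[t] - grand) ** 2).sum())
        df[t] = levels[t] - 1
    for t1, t2 in (("S1", "S2"), ("S1", "S3"), ("S2", "S3")):
        c1, c2 = factors[t1], factors[t2]
        mm = _means([c1, c2])
        dev = (
            mm
            - main_means[t1].reindex(mm.index.get_level_values(0)).to_numpy()
            - main_means[t2].reindex(mm.index.get_level_values(1)).to_numpy()
            + grand
        )
        weight = n_total / (levels[t1] * levels[t2])
        term = f"{t1}*{t2}"
        ss[term] = float(weight * (dev ** 2).sum())
        df[term] = (levels[t1] - 1) * (levels[t2] - 1)

    model_terms = ["S1", "S2", "S3", "S1*S2", "S1*S3", "S2*S3"]
    ss["Error"] = ss_total - sum(ss[t] for t in model_terms)
    df["Error"] = (n_total - 1) - sum(df[t] for t in model_terms)
    ss["Total"] = ss_total
    df["Total"] = n_total - 1

    rows = []
    mse = ss["Error"] / df["Error"] if df["Error"] > 0 else np.nan
    for term in model_terms + ["Error", "Total"]:
        ms = ss[term] / df[term] if term != "Total" and df[term] > 0 else np.nan
        if term in model_terms and np.isfinite(mse) and mse > 0:
            fval = ms / mse
            pval = float(f_dist.sf(fval, df[term], df["Error"]))
        else:
            fval = pval = np.nan
        rows.append(
            {"term": term, "sum_sq": ss[term], "df": df[term], "mean_sq": ms, "F": fval, "p": pval}
        )
    out = pd.DataFrame(rows).set_index("term")
    out.loc["Total", ["mean_sq", "F", "p"]] = np.nan
    out.loc["Error", ["F", "p"]] = np.nan
    return out


def marginal_means_comparison(
    records: pd.DataFrame,
    alpha: float = 0.05,
    reference_cell: Tuple[str, int, str] = ("greedy", 3, "bikmeans"),
    response: str = "ta",
    top_n: int = 12,
) -> pd.DataFrame:
    """Tukey-Kramer comparison of per-cell mean accuracies.

    Each (algorithm, k, discretizer) cell's mean response gets a
    simultaneous confidence interval built from the ANOVA error mean square;
    ``significant_vs_reference`` flags cells whose mean differs from the
    reference cell at family level ``alpha``; ``top`` marks the ``top_n``
    cells by mean response.
    """
    data = _check_balanced(records, response)
    table = anova3(records, response)
    mse = float(table.loc["Error", "mean_sq"])
    dferr = int(table.loc["Error", "df"])
    cells = (
        data.groupby(["algorithm", "k", "discretizer"], observed=True)[response]
        .agg(["mean", "count"])
        .reset_index()
    )
    key = (str(reference_cell[0]), int(reference_cell[1]), str(reference_cell[2]))
    ref = cells[
        (cells["algorithm"] == key[0])
        & (cells["k"] == key[1])
        & (cells["discretizer"] == key[2])
    ]
    if ref.empty:
        raise ValidationError(f"reference cell {reference_cell!r} not present in the design")
    ref_mean = float(ref["mean"].iloc[0])
    ref_n = int(ref["count"].iloc[0])
    q = studentized_range.ppf(1 - alpha, len(cells), dferr)
    half = q / np.sqrt(2) * np.sqrt(mse * (1.0 / cells["count"] + 1.0 / ref_n))
    ci_half = q / np.sqrt(2) * np.sqrt(mse / cells["count"])
    cells["ci_low"] = cells["mean"] - ci_half
    cells["ci_high"] = cells["mean"] + ci_half
    cells["diff_vs_reference"] = cells["mean"] - ref_mean
    cells["significant_vs_reference"] = np.abs(cells["diff_vs_reference"]) > half
    cells.loc[
        (cells["algorithm"] == key[0])
        & (cells["k"] == key[1])
        & (cells["discretizer"] == key[2]),
        "significant_vs_reference",
    ] = False
    cells["rank"] = cells["mean"].rank(ascending=False, method="first").astype(int)
    cells["top"] = cells["rank"] <= top_n
    return cells.sort_values("rank").reset_index(drop=True)


def summarize(
    records: pd.DataFrame,
    plot_dir=None,
) -> pd.DataFrame:
    """Group means/sds of sn/sp/ta by (algorithm, discretizer, k).

    When ``plot_dir`` is given, scatter plots of (Sn, TA) and (Sp, TA)
    colored by discretizer are written there (requires matplotlib).
    """
    cols = [c for c in ("sn", "sp", "ta") if c in records.columns]
    summary = (
        records.groupby(["algorithm", "discretizer", "k"], observed=True)[cols]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    if plot_dir is not None:
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        for xcol, fname in (("sn", "sn_vs_ta.png"), ("sp", "sp_vs_ta.png")):
            fig, ax = plt.subplots(figsize=(6, 5))
            for method, grp in records.groupby("discretizer", observed=True):
                ax.scatter(grp[xcol], grp["ta"], s=8, alpha=0.6, label=method)
            ax.set_xlabel(xcol.capitalize())
            ax.set_ylabel("Total accuracy")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(plot_dir / fname, dpi=150)
            plt.close(fig)
    return summary
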