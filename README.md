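# grndisc

Discretization of time-course gene-expression matrices and benchmarking of
its effect on gene-regulatory-network (GRN) inference.

The package provides:

* **Five unsupervised discretizers** mapping a genes × time-points matrix to
  integer levels `1..k`: equal-width (`ewd`), equal-frequency (`efd`),
  per-gene 1-D k-means (`kmeans`), per-time-point 1-D k-means (`cokmeans`),
  and bidirectional k-means (`bikmeans`), which runs row and column k-means
  at `k+1` levels and combines them cell-wise by the product rule
  `x² ≤ rowlabel·collabel < (x+1)²`. The 1-D k-means subproblem is solved
  *exactly* by dynamic programming, so all discretizers are deterministic.
* **Three network-inference algorithms** on discretized data: K2 (greedy
  parent selection under a node order derived from each gene's time of
  initial ≥1.2-fold up- / ≤0.7-fold down-regulation), first-ascent greedy
  DAG search (BIC or marginal-likelihood score), and an ARACNE-style
  pipeline (pairwise mutual information, χ² significance threshold,
  Data Processing Inequality pruning; defaults `p = 1e-7`, `t = 0.15`).
* **Evaluation** of inferred vs. true networks: Tp/Tn/Fp/Fn over the
  directed (or undirected) gene-pair universe and the derived sensitivity,
  specificity and total accuracy.
* **A synthetic benchmark generator**: ground-truth acyclic networks plus
  positive expression matrices with lagged, saturating regulator→target
  signal and Gaussian noise (default shape 50 genes × 25 time points ×
  100 datasets), fully reproducible from a single seed.
* **A factorial benchmark driver**: algorithm × discretizer × interval-count
  sweeps, balanced three-way ANOVA of total accuracy (main effects + all
  two-way interactions), and Tukey–Kramer marginal-means comparison.

## Command line

```bash
# generate a reproducible benchmark suite
grndisc simulate --out-dir suite --n-datasets 100 --n-genes 50 --n-timepoints 25 --seed 1

# discretize one matrix
grndisc discretize --method bikmeans --k 3 --in suite/ds000_expression.tsv --out levels.tsv

# infer a network (K2 needs the raw matrix for node ordering)
grndisc infer --algorithm k2 --in levels.tsv --k 3 --expr suite/ds000_expression.tsv --out net.tsv
grndisc infer --algorithm aracne --in levels.tsv --k 3 --p 1e-7 --t 0.15 --out net2.tsv

# score against the ground truth
grndisc evaluate --inferred net.tsv --truth suite/ds000_network.tsv

# full sweep + statistics
grndisc benchmark --suite-dir suite --ks 2,3,4 --out records.tsv
grndisc benchmark-stats --in records.tsv --anova anova.tsv \
    --compare compare.tsv --reference greedy,3,bikmeans
```

File formats are plain TSV: expression/level matrices with a header row of
time labels and gene ids in the first column; networks as two-column
`regulator → target` edge lists (with a `# genes:` comment preserving the
gene universe) or SIF (`regulator regulates target`).

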