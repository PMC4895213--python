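# depna

Dependency network analysis (DEPNA) for multivariate time series:
directed node-influence measures built from partial correlations, with a
linear-dynamical-system BOLD simulator for validating them and
statistical tools for comparing two experimental conditions.

## The problem

Functional connectivity studies of fMRI usually stop at symmetric
correlation graphs: they say which regions co-fluctuate, not which
region *drives* the network's correlation structure. DEPNA assigns every
node a directed influence score using only zero- and first-order
correlations, so it needs none of the temporal-resolution assumptions
that Granger-style methods do. It was first developed for financial
networks and is used here for task fMRI region-of-interest panels, but
applies to any nodes-by-time panel.

## The method

For nodes with signals `X_i(t)`, let `C(i,k)` be the Pearson correlation
and

    PC(i,k|j) = (C(i,k) − C(i,j)·C(k,j)) / sqrt((1 − C(i,j)²)(1 − C(k,j)²))

the partial correlation of `i` and `k` given `j`. The **correlation
influence** of node `j` on the pair `(i,k)` is

    d(i,k|j) = C(i,k) − PC(i,k|j),

the share of the `i–k` correlation explained by `j`. Averaging over the
conditioning targets gives the asymmetric **dependency matrix**

    D(i,j) = mean over k ∉ {i,j} of d(i,k|j),

with negative (suppressor) influences reset to zero per triple before
averaging (absolute-value and signed modes are available). Column and
row sums of `D` are each node's

* **Influencing Degree** — `sum_i D(i,j)`: how much `j` drives all other
  pairwise correlations, and
* **Influenced Degree** — `sum_i D(j,i)`: how much the rest of the
  network drives `j`.

Two conditions are compared per node (paired t on the degrees, BH-FDR
across nodes at q ≤ 0.05), per dependency edge (paired t on Fisher-Z
values, raw p < 0.001 by default), and per edge-influencer (FDR across
the N−2 conditioning nodes). The method ranks correlational influence;
it does not infer causal direction in the strict sense.

The simulator generates block-design BOLD from the standard linear
forward model `dz/dt = (A z + W u)/σ` (neural lag σ = 50 ms, within-
region decay −1 on the diagonal of `A`), convolves with a canonical
double-gamma HRF, adds thermal noise `N(0.1, 0.9²)` and samples at
TR = 2.2 s. Chain, two-leg, feedback-cycle and slowed-decay topologies
are built in, with the benchmark design of 20 subjects × 10 blocks of
22 s.

## Worked example

```python
from depna import DEPNA, build_chain, simulate_study

study = simulate_study(build_chain(4, 0.4), n_subjects=1, seed=0)
panel = study.panels[0][0]          # one 22 s block + rest, 20 TRs
res = DEPNA(panel).fit()
print(res.summary())
```

```
Dependency Network Analysis
  nodes: 4   timepoints: 20   negative mode: clip_to_zero

      influencing  influenced
node
A          3.2511      0.9351
C          1.7166      1.6062
B          1.5786      1.7500
D          0.1492      2.4043
```

Region A — the region receiving the stimulus, which drives the chain
A→B→C→D — has the highest Influencing Degree (3.25) and the lowest
Influenced Degree (0.94); terminal region D is the most influenced
(2.40) and influences almost nothing (0.15). A single noisy block ranks
B and C imperfectly; averaging the full 20-subject × 10-block study
recovers the strict hierarchy A>B>C>D (`run_simulation_experiment`
("chain_sweep")).

Condition comparisons follow the same model/results pattern:

```python
from depna import DEPNAComparison
res = DEPNAComparison(panels_condition_a, panels_condition_b).fit()
print(res.summary())              # significant nodes, passing edges
res.edge_influences(("A", "C"))   # who changed the A–C correlation?
```

A command-line interface mirrors the library: `depna compute` (panel →
matrices + degrees), `depna simulate` (scenario config → summary table
and optional panel files), `depna compare` (two manifests → tables,
GraphML and BrainNet Viewer `.node`/`.edge` exports), `depna fixtures`
(small example study).

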