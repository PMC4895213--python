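# Methods

## The dependency-network model

DEPNA summarizes a panel of node signals (regions × timepoints) by how
much each node explains the correlations among the others. All
quantities derive from the Pearson correlation matrix `C`:

* first-order partial correlation
  `PC(i,k|j) = (C(i,k) − C(i,j)C(k,j)) / sqrt((1−C(i,j)²)(1−C(k,j)²))`;
* correlation influence `d(i,k|j) = C(i,k) − PC(i,k|j)`, which is large
  only when a substantial share of the `i–k` correlation runs through
  `j` (it is *not* inflated when all three correlations are small);
* dependency matrix `D(i,j) = mean_{k∉{i,j}} d(i,k|j)`, the average
  influence of `j` on `i`'s correlations;
* Influencing Degree (column sums of `D`) and Influenced Degree (row
  sums).

Assumptions: signals are stationary within a panel, relationships are
approximately linear, and each node has nonzero variance. The measure
ranks correlational influence; it does not establish causal direction.

### Conventions the definition leaves open

* **Averaging set.** Triples with `k ∈ {i,j}` are undefined under the
  partial-correlation formula, so `D(i,j)` averages over the `N−2`
  valid conditioning targets with divisor `N−2`. Divisors `N−1` and
  `N` (which treat degenerate triples as zero terms) are available via
  the `divisor` argument; they rescale `D` uniformly and change no
  ranking.
* **Negative influences.** Suppressor triples (`d < 0`) are reset to
  zero *per triple, before averaging*, so a node's few negative triples
  cannot cancel its positive ones. `absolute` (sum of magnitudes) and
  `signed` (no treatment) modes are provided for diagnostics.
* **Diagonal.** Self-influence is meaningless under the triple
  formula; `D` has an exactly zero diagonal.
* **Singular triples.** If a conditioning node is perfectly correlated
  with a triple member the denominator vanishes; this raises a
  `SingularTripleError` naming the triple. Real data essentially never
  hits it; duplicated synthetic rows should fail loudly rather than
  produce quiet garbage. An opt-in `screen_jitter` mode additionally
  treats `|C| > 1 − 1e-9` as singular.
* **Tolerances.** Pair symmetry of `d(i,k|j)` is exact to 1e-12 and
  degree conservation (`sum influencing = sum influenced = sum D`) to
  1e-10; with `N` up to a few hundred nodes double-precision
  accumulation stays orders of magnitude below these bounds.
* **Complexity.** The triple tensor is O(N³) but `D` is reduced one
  conditioning node at a time, so memory stays O(N²);
  `compute_influence_tensor` materializes the full tensor only on
  request.

## The BOLD simulator

The simulator exists to validate hierarchy recovery: it generates data
from a network whose true direction of influence is known.

Neural dynamics follow the linear DCM-style forward model

    dz/dt = (A z + W u(t)) / σ

with σ = 0.05 s (the neural lag, a time constant), directed connection
strengths in `A[target, source] ∈ [0, 1]`, within-region decay −1 on
the diagonal (−1/m for a region slowed by factor m), and the
block-design stimulus `u` fed to the first region only. Integration is
forward Euler at dt = 10 ms (configurable); with σ = 50 ms and |A| ≤ 1
the scheme is stable, and a step-halving test bounds the discretization
error below 1% of signal scale. Stability of `A` (eigenvalue real
parts < 0) is checked before integrating.

BOLD is `y = HRF * z + n`: convolution with a canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions, ratio
1/6, 32 s support), additive white thermal noise `N(0.1, 0.9²)`, then
decimation to TR = 2.2 s.

**HRF gain convention.** The kernel holds the raw density-difference
samples and the convolution is a plain discrete sum, giving a
steady-state gain of (kernel area)/dt ≈ 83 at dt = 10 ms. This is a
deliberate choice of operating regime: against noise sd 0.9 it makes
upstream regions strongly super-threshold while regions far down a
chain (signal amplitude ∝ strength^k) sit near the noise floor. In
that regime the degree measures produce scores of order 0.1–3 — the
scale on which they are reported for real data — and the Influenced
Degree of terminal regions becomes SNR-limited, which is why the
standard design doubles the stimulus amplitude (`input_scale = 2`) for
all Influenced-Degree runs. A unit-area kernel (gain ≤ 1) would leave
every region below the noise floor at these noise settings and no
ordering would be recoverable.

**Study design.** Defaults are 20 subjects × 10 blocks; each block is
22 s of stimulation followed by 22 s of rest (rest length is a free
parameter; equal-to-block is the default so the signal returns to
baseline between blocks). The degree scores are computed **per block**,
on the block's 10 TR samples plus the following rest's 10 samples (20
samples per panel — a single TR cannot carry a correlation), yielding
200 scores per study whose mean and SEM are reported. SEM is taken
over all 200 scores rather than over 20 subject means; with noise
independent across blocks the two differ little, and the per-score SEM
is the more conservative yardstick for the between-topology contrasts.

**Randomness.** One master seed; per-subject noise streams are spawned
by index (`SeedSequence.spawn`), so enlarging a study never reshuffles
earlier subjects, and regenerating with the same seed is bit-for-bit
identical. The noise-free trajectory is shared across subjects (the
paradigm is deterministic); subjects differ only in thermal noise.

**What the generator does not emulate:** nonlinear (balloon-model)
hemodynamics, HRF variability across regions, physiological noise,
per-node stochastic neural input, scanner drift, or motion. Passing
recovery tests on these data therefore shows the measures track the
designed influence structure under thermal noise — not that they are
robust to every artifact of real fMRI.

### Simulation findings at the standard design

With the default design the package's own experiments
(`run_simulation_experiment`) show: strict chain hierarchy A>B>C>D in
mean Influencing Degree at every strength 0.2–0.5; rising Influenced
Degree down the chain under doubled input (terminal region maximal from
strength ≈ 0.4 up); a two-leg source gaining roughly 60 SEM of
Influencing Degree over its one-leg value; a ten-fold decay slowdown
on the terminal region raising its Influencing Degree by roughly 35
SEM. Closing a 3-region chain with C→A feedback raises C's mean
Influencing Degree only by ~0.1–0.7 SEM, below any reasonable
detection threshold at this design: with σ = 50 ms every inter-region
transfer is two orders of magnitude faster than TR = 2.2 s, so sampled
BOLD waveforms are amplitude-scaled copies of one waveform and the
loop's only surviving signature is the geometric amplitude gain
1/(1−s³) ≈ 1.07 at s = 0.4. The effect's *direction* is consistently
positive, but detecting it at 20 subjects would require either much
slower neural dynamics or far more data; the acceptance script reports
the measured effect size in SEM units.

## The comparison stage

Per-subject degree profiles and dependency matrices from two matched
conditions are compared with paired two-tailed t tests (Welch tests
for unpaired group designs, `paired=False`):

* **degrees** — tested on the raw scale (they are sums and routinely
  exceed 1), BH-FDR across nodes per measure, default q ≤ 0.05;
* **dependency edges** — Fisher-Z transformed (correlation-like,
  bounded by 1; inputs clipped to ±(1 − 1e-6) so boundary values stay
  finite), thresholded on raw p, default 0.001 (0.05 is also in use;
  the threshold is a parameter), edge direction influencer → target;
* **edge influences** — for a chosen pair, the N−2 conditioning nodes'
  `d` values, Fisher-Z, BH-FDR across influencers per edge.

t > 0 always means condition `a` exceeds condition `b`. When the
differences have zero variance *and* zero mean (identical inputs) the
test returns t = 0, p = 1 rather than NaN. Null calibration at the
default design (white-noise panels, 20 subjects, 200 repetitions)
gives a familywise node-rejection rate ≈ 0.02–0.05 and an edge
rejection rate at or below its nominal 0.001 (the Fisher-Z of clipped
dependency values is slightly discrete under the null, which makes the
edge test conservative).

## Signal preparation

`principal_eigenvariate` reduces a voxel × time matrix to its first
right singular vector after row-centering, scaled by the singular
value over √voxels (the dominant fMRI convention) and signed to
correlate nonnegatively with the mean voxel course.
`average_condition_blocks` combines repeated equal-length blocks by
pointwise mean (concatenation is available as an alternative); the
mean of block-locked signals raises SNR by √n_blocks.

## Problem sizes

The unit suite runs the full 20 × 10 study design for the topology
contrasts and reduced designs (2–8 subjects, 1–2 blocks) elsewhere;
oracle checks use 5-node, 200-timepoint Gaussian panels (100 seeds) and
null calibration uses 200 repetitions of 20-subject studies. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* Influence is correlational: a node can score high by being a common
  output as well as a common cause.
* First-order conditioning only; joint influence of node sets is out
  of scope.
* Clipping negative influences biases degree sums slightly upward on
  null data (the noise floor: ≈ 0.05 per node at N = 4, T = 20,
  shrinking with T).
* The paired t tests assume approximately normal subject-level
  differences; no permutation or mixed-model alternatives are
  provided.
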