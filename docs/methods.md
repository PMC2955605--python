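# Methods

## Inference model

The method infers the *conservative causal core* of a gene regulatory
network: the subnetwork formed when each gene contributes at most its
single strongest significant interaction.

1. **MI estimation.** All n(n−1)/2 pairwise mutual-information values
   are estimated. The default estimator copula-transforms each gene row
   (value → rank/(m+1), average ranks for ties, so outputs lie strictly
   in (0,1)) and applies the parametric Gaussian form
   I = −½ log(1 − ρ²) (nats). An alternative B-spline estimator
   assigns each sample fuzzy membership weights over `bins` bins per
   variable using B-spline basis functions of a given order (knots
   uniform after min-max scaling; `bins` = 10 and order 3 by default)
   and computes plug-in MI (bits) from the weight-averaged marginal and
   joint probabilities; order 1 reduces exactly to hard-binned histogram
   MI. The B-spline estimator bins raw values by default; a flag applies
   the copula transform first, since conventions differ on whether raw
   or rank-normalized intensities are binned.
2. **Significance.** The null hypothesis per pair is I = 0. A *pooled*
   permutation null is built: in each of `n_permutations` (default 100)
   rounds every gene row is shuffled independently and all pairwise MI
   values are pooled, giving n_permutations·n(n−1)/2 null values. The
   threshold I₀ is the empirical (1−α) order-statistic quantile
   (α = 0.05 default); significance is the strict inequality I > I₀,
   so threshold ties are non-significant. Pooling gives one global
   threshold — per-pair nulls at genome scale are computationally
   prohibitive and a single matrix-wide cutoff is standard usage. No
   multiple-testing correction by default; Bonferroni is available.
3. **Maximization.** Each gene with a nonempty significant neighborhood
   selects its maximum-MI neighbor (argmax ties broken toward the
   smallest index — deterministic, and reachable only with discrete
   estimators or constructed data). The per-gene choices form a directed
   contribution matrix, retained as a diagnostic; its symmetrization is
   the inferred undirected network, which therefore has at most n edges.

MI matrices store a zero diagonal and every operation excludes
self-pairs. Degenerate pairs (flat probes, perfect linear dependence)
are reported as MI 0 with a warning rather than aborting a whole-matrix
computation.

## Baselines

* **RN** keeps all pairs with I above the threshold.
* **ARACNE** prunes RN with the data processing inequality: in every
  fully connected triplet, edge (i,j) is removed when
  I_ij < (1−eps)·min(I_ik, I_jk). The tolerance is multiplicative
  (eps = 0.1 default) and removals are computed on the original matrix
  and applied simultaneously, so triplet scan order is irrelevant.
* **CLR** rectifies each MI value against the row statistics of both
  endpoints: z_i(j) = max(0, (I_ij − μ_i)/σ_i), weight =
  √(z_i(j)² + z_j(i)²). Genes with zero row spread contribute zero.
* **MRNET** runs greedy maximum-relevance/minimum-redundancy forward
  selection per target: repeatedly pick the candidate j maximizing
  s_j = I_jt − mean_{k∈selected} I_jk, record s_j, stop when the best
  score is ≤ 0; undirected weights are the max of the two directions.

## Benchmark protocol

To compare the *methods* rather than their thresholding heuristics, each
method exposes an edge-score matrix and is evaluated at the cutoff
maximizing its F-score against the known truth (`optimal_cutoff`):
RN's scores are the MI values; ARACNE's are MI values with DPI-pruned
pairs zeroed (DPI applied once to the dense matrix); the conservative
core's scores keep only each gene's maximal MI entry, symmetrized —
thresholding that matrix at t provably reproduces the full inference run
with significance threshold t, because if a gene's global maximum is
below t its whole neighborhood is. Candidate thresholds are all distinct
positive score values (edges are pairs scoring ≥ the candidate) plus one
above the maximum; zero scores never form edges, so zero is not a
candidate. F ties go to the densest maximizer. Ensembles are summarized
by max/min/mean/median F, and per-true-edge mean TPR uses the bins
black (0.75, 1], blue (0.5, 0.75], green (0.25, 0.5], red [0, 0.25].

When an evaluation is restricted to a candidate mask (e.g. regulator ×
target pairs only), inferred edges outside the mask are discarded before
counting — counting them as false positives would silently change
precision. The F-score of an empty network is defined as 0.

## Simulator

The generator emulates the documented behavior of steady-state
transcription simulators (subnetwork sampling by neighbor addition,
Michaelis–Menten/Hill transfer functions, noise, per-dataset parameter
resampling) without reproducing any particular tool bit-for-bit, so
absolute F-scores from other studies are not comparable; method
*orderings* are.

* **Source topology**: the first `n_tfs` genes are transcription
  factors; each later TF is regulated by one earlier TF (keeping the
  graph weakly connected and acyclic), and every non-TF gene attaches to
  1–3 TFs chosen by preferential attachment (P ∝ out-degree + 1),
  giving right-skewed out-degrees with hubs. Edge signs are random
  (70% activation).
* **Subnetwork sampling**: neighbor addition — grow from one random
  seed node by uniformly drawing from the undirected neighborhood of the
  current set; the induced subnetwork is connected.
* **Expression**: root genes draw activity uniformly on (0,1) per
  sample (the steady-state analogue of varying experimental
  conditions). Each downstream gene, in topological order, takes
  b + V·Π(Hill terms): x^h/(K^h+x^h) per activator, K^h/(K^h+x^h) per
  repressor; multiple regulators combine multiplicatively (independent
  binding). Multiplicative lognormal noise exp(N(0, σ²)) is applied to
  each computed level **and the noisy level is what downstream
  regulators see**. Propagating the intrinsic noise is essential: if
  noise were applied only to the final observations, a monotone
  regulatory chain would be deterministic end to end, indirect pairs
  would carry as much MI as direct ones, and the data processing
  inequality would have nothing to work with. Cyclic models are
  rejected — the closed-form topological evaluation is the only fully
  specified steady state; fixed-point iteration would introduce
  unstated convergence choices.
* **Default kinetic ranges** (unit activity scale): V ∈ [0.5, 1.5],
  K ∈ [0.2, 0.8], h ∈ {1, 2, 3}, b ∈ [0, 0.05], σ ∈ [0.05, 0.2]; all
  overridable. Ensembles redraw every kinetic parameter per dataset
  from these ranges, with per-dataset seeds spawned deterministically
  from the ensemble seed, so everything is bitwise reproducible.

What the simulator does **not** emulate: time-course dynamics, the
mRNA/protein distinction, saturating measurement technology (microarray
compression), batch effects, and the empirical topology of any real
organism's curated network. Passing benchmarks on these data therefore
demonstrate correct mechanics and relative method behavior under
Hill-kinetics steady states, not absolute performance on microarrays.

## Problem sizes used in the shipped checks

The ensemble benchmark in the test suite uses one 100-gene subnetwork
sampled from a 250-gene source (35 TFs), 50 datasets of 200 samples,
seed fixed — enough for stable medians across the ensemble. The
significance-calibration check uses 20 independent genes × 100 samples
with 100 permutation rounds at α = 0.05, asserting the significant
fraction within three binomial standard errors of α. Oracle-equivalence
checks fuzz 5–8-gene instances against independent loop-based
transcriptions of each method.

## Numerical choices

* Gaussian MI uses `log1p(−ρ²)` and clips tiny negatives to 0;
  |ρ| ≥ 1 − 1e−12 raises (singular covariance).
* The vectorized MI matrix is explicitly symmetrized to remove
  last-bit asymmetry from the BLAS correlation path.
* The empirical quantile is the type-1 (order statistic) definition:
  the k-th smallest pooled value, k = ⌈(1−α)·N⌉.
* B-spline domain: data min-max scaled to [0, bins − order + 1]; the
  maximum sample is nudged one ulp inside the support of the last basis
  function.
* Gene indices are 0-based internally; all user-facing partner reports
  are 1-based with 0 meaning "no partner".

## Known limitations

* The conservative core bounds recall by construction (≤ n edges); it is
  a precision-oriented method and the F-score comparison reflects that
  trade-off, not full-network recovery.
* The pooled permutation null treats pairs exchangeably; genes with
  unusual marginals (heavy ties) can be slightly mis-calibrated.
* CLR is implemented in its rectified two-sided z form only.
* The simulator's acyclicity requirement excludes feedback loops, which
  real transcriptional networks contain.
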