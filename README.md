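# c3net

Conservative causal core inference of gene regulatory networks from
expression data, together with the classical mutual-information baselines
(RN, ARACNE, CLR, MRNET), permutation significance testing, a
steady-state expression simulator, and ensemble benchmark evaluation.

## The problem and the method

Given a genes × samples expression matrix, information-theoretic network
inference estimates the mutual information

I(X, Y) = Σ p(x, y) log [ p(x, y) / (p(x) p(y)) ]

for every gene pair and turns the significant values into an undirected
network. Dense thresholding (the relevance-network approach) accumulates
false positives among co-regulated genes; post-processing with the data
processing inequality (ARACNE) or background z-scores (CLR) prunes some
of them. The conservative-core method takes the opposite, extremal
route: after a permutation significance test of all pairwise MI values
produces a binary connectivity mask C, each gene i with significant
neighborhood N(i) = { j : C_ij = 1, j ≠ i } contributes exactly one
edge — the one to

j\*(i) = argmax_{j ∈ N(i)} I_ij,

and the union of these per-gene choices, symmetrized, is the inferred
network. A gene with no significant neighbor contributes nothing. The
result has **at most as many edges as genes** and targets the core of
strongest interactions rather than the full network: fewer edges, but
each backed by its endpoint's strongest statistical dependence, which is
what you want when every predicted interaction costs a bench experiment.

MI is estimated either with the copula-transformed parametric Gaussian
estimator, I = −½ log(1 − ρ²) in nats (fast, monotone-invariant), or
with a B-spline fuzzy-binning histogram estimator in bits.

## Worked example

```python
import numpy as np
from c3net import MIMatrix, ConnectivityMatrix, select_partners, build_adjacency

I = np.array([[0.0, 0.7, 0.9, 0.8],
              [0.7, 0.0, 0.6, 0.5],
              [0.9, 0.6, 0.0, 0.1],
              [0.8, 0.5, 0.1, 0.0]])
C = np.array([[0, 1, 1, 1],
              [1, 0, 1, 0],
              [1, 1, 0, 0],
              [1, 0, 0, 0]])

partners = select_partners(MIMatrix(list("1234"), I), ConnectivityMatrix(list("1234"), C))
print(partners.as_one_based())        # [3 1 1 1]
net = build_adjacency(partners)
print(net.adjacency)
# [[0 1 1 1]
#  [1 0 0 0]
#  [1 0 0 0]
#  [1 0 0 0]]
```

Gene 1's strongest significant partner is gene 3 (MI 0.9); genes 2, 3
and 4 all pick gene 1. Although each gene adds at most one edge, the
symmetrized result is a star in which gene 1 has degree 3 — per-gene
conservativeness does not cap the final degree of a hub.

Longer narrative scripts live in `examples/`: the worked example, full
inference on simulated data, the ensemble benchmark of all five methods,
and per-edge inferability analysis. A thin CLI (`c3net infer`,
`c3net simulate`, `c3net benchmark`, `c3net evaluate`) wraps the same
functions for shell use; every run writes a JSON manifest with its full
configuration and seed.

## Benchmarking with simulated ensembles

`c3net.simulator` samples subnetworks from a synthetic source regulatory
topology by neighbor addition and generates steady-state expression via
Michaelis–Menten/Hill transfer functions with propagated multiplicative
noise. `benchmark_ensemble` evaluates each method at the threshold
maximizing its F-score, F = 2pr/(p + r), against the known truth, over an
ensemble whose kinetic parameters are redrawn per dataset. A typical run
(`examples/benchmark_ensemble.py`, 50 genes, 20 datasets of 200 samples)
prints:

```
method       max     min    mean  median
c3net     0.8776  0.7191  0.8029  0.7915
rn        0.5000  0.4103  0.4560  0.4547
aracne    0.7612  0.5000  0.6381  0.6315
clr       0.6275  0.4426  0.5522  0.5568
mrnet     0.8081  0.6731  0.7606  0.7625
```

The conservative core leads on every summary statistic here; the margin
reflects its suppression of the false positives that MI thresholding
otherwise places between co-regulated siblings.

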