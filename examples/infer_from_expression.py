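"""Full inference pipeline on simulated steady-state expression data.

Simulates a small regulatory network, estimates all pairwise MI values
(copula transform + Gaussian estimator), thresholds them with a pooled
permutation null, and runs the per-gene maximization.  Compares the
inferred edges against the ground truth.
"""

from c3net import (
    c3net_infer,
    compare_networks,
    make_source_network,
    sample_subnetwork,
    simulate_expression,
)

source = make_source_network(n_genes=60, n_tfs=10, rng_seed=7)
model = sample_subnetwork(source, n=25, rng_seed=8)
truth = model.true_network()
print(f"true network: {model.n_genes} genes, {truth.n_edges} edges")

expr = simulate_expression(model, p=200, rng_seed=9)
network = c3net_infer(expr, alpha=0.05, n_permutations=100, rng_seed=10)
print(f"inferred network: {network.n_edges} edges (at most one per gene)")

result = compare_networks(network, truth)
print(
    f"TP={result.TP} FP={result.FP} FN={result.FN} "
    f"precision={result.precision:.2f} recall={result.recall:.2f} "
    f"F={result.fscore:.2f}"
)
# The method is conservative: few edges, high precision, recall limited
# by design to each gene's single strongest interaction.
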