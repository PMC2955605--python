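"""Permutation significance testing of pairwise mutual information.

The null hypothesis for each gene pair is I = 0 (independence).  A global
pooled permutation null is used: in each permutation round every gene
row's samples are shuffled independently, destroying all between-gene
dependence while preserving each marginal, and all pairwise MI values of
the shuffled matrix are pooled.  The significance threshold I0 is the
empirical (1 - alpha) quantile of the pooled null, and a single threshold
is applied to the whole MI matrix.  Per-pair nulls would be prohibitive at
genome scale and the pooled null matches single-threshold usage.

No multiple-testing correction is applied by default; a Bonferroni option
(alpha divided by the number of tested pairs) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, ExpressionMatrix, MIMatrix
from .mi import mi_matrix

__all__ = ["NullModel", "build_null", "threshold_connectivity"]


@dataclass
class NullModel:
    """Pooled permutation null of pairwise MI values.

    ``threshold_I0`` is the empirical (1 - alpha) quantile of
    ``null_values`` (type-1 / order-statistic definition: the k-th
    smallest value with k = ceil((1 - alpha) * N)).
    """

    null_values: np.ndarray  # sorted ascending
    n_permutations: int
    alpha: float
    threshold_I0: float

    def quantile_threshold(self, alpha: float) -> float:
        """Empirical (1 - alpha) order-statistic quantile of the null."""
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        n = self.null_values.size
        k = max(1, math.ceil((1.0 - alpha) * n))
        return float(self.null_values[k - 1])


def build_null(
    expr: ExpressionMatrix,
    estimator: str = "gaussian",
    n_permutations: int = 100,
    alpha: float = 0.05,
    rng_seed: int = 0,
    bonferroni: bool = False,
    **estimator_params,
) -> NullModel:
    """Build the pooled permutation null for an expression matrix.

    Each of ``n_permutations`` rounds shuffles every gene row
    independently and pools all n(n-1)/2 pairwise MI values of the
    shuffled matrix, so the null holds n_permutations * n(n-1)/2 values.
    Reproducible given ``rng_seed``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation round")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    n = expr.n_genes
    iu = np.triu_indices(n, k=1)
    pooled = np.empty(n_permutations * iu[0].size)
    for r in range(n_permutations):
        shuffled = np.array(
            [rng.permutation(expr.values[i]) for i in range(n)]
        )
        perm_expr = ExpressionMatrix(list(expr.gene_ids), shuffled)
        mi = mi_matrix(perm_expr, estimator=estimator, **estimator_params)
        pooled[r * iu[0].size : (r + 1) * iu[0].size] = mi.values[iu]
    pooled.sort()
    effective_alpha = alpha
    if bonferroni:
        effective_alpha = alpha / iu[0].size
    model = NullModel(
        null_values=pooled,
        n_permutations=n_permutations,
        alpha=alpha,
        threshold_I0=0.0,
    )
    model.threshold_I0 = model.quantile_threshold(effective_alpha)
    return model


def threshold_connectivity(mi: MIMatrix, threshold: float) -> ConnectivityMatrix:
    """Binary significance mask: C[i, j] = 1 iff I[i, j] > threshold, i != j.

    The inequality is strict, so ties at the threshold are non-significant
    (deterministic and conservative).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    conn = (mi.values > threshold).astype(np.int8)
    np.fill_diagonal(conn, 0)
    return ConnectivityMatrix(list(mi.gene_ids), conn)
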