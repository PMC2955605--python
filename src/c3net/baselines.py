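"""The four mutual-information baseline inference methods.

* RN (relevance network): keep every statistically significant pair.
* ARACNE: RN followed by data-processing-inequality pruning — in every
  fully connected triplet the weakest edge is removed, with a
  multiplicative tolerance eps.
* CLR (context likelihood of relatedness): background-correct each MI
  value into a z-score against the row statistics of both endpoint genes.
* MRNET: per-target greedy maximum-relevance / minimum-redundancy forward
  selection of regulators.

All four are deterministic functions of the MI matrix.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import MIMatrix, Network, ScoredNetwork
from .significance import threshold_connectivity

__all__ = ["rn", "aracne", "aracne_scores", "clr", "mrnet"]

logger = logging.getLogger(__name__)


def rn(mi: MIMatrix, threshold: float) -> Network:
    """Relevance network: all pairs with MI strictly above the threshold."""
    conn = threshold_connectivity(mi, threshold)
    return Network(list(mi.gene_ids), conn.values)


def _dpi_removals(weights: np.ndarray, adj: np.ndarray, eps: float) -> np.ndarray:
    """Boolean matrix of edges failing the DPI in some present triangle.

    Edge (i, j) is marked when a node k closes a triangle with both i and
    j and I_ij < (1 - eps) * min(I_ik, I_jk).  All triangles are scanned
    on the original matrix and removals applied simultaneously, so scan
    order cannot change the result.
    """
    n = weights.shape[0]
    w = np.where(adj > 0, weights, 0.0)
    remove = np.zeros((n, n), dtype=bool)
    scale = 1.0 - eps
    for k in range(n):
        nbrs = adj[k] > 0
        if nbrs.sum() < 2:
            continue
        wk = np.where(nbrs, w[k], 0.0)
        # triangle (i, j, k): need edges i-k, j-k (outer) and i-j (adj)
        both = np.outer(nbrs, nbrs)
        min_ik_jk = np.minimum.outer(wk, wk)
        remove |= both & (adj > 0) & (w < scale * min_ik_jk)
    np.fill_diagonal(remove, False)
    return remove


def aracne(mi: MIMatrix, threshold: float, eps: float = 0.1) -> Network:
    """ARACNE: relevance network pruned by the data processing inequality."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    base = rn(mi, threshold)
    remove = _dpi_removals(mi.values, base.adjacency, eps)
    adj = base.adjacency.copy()
    adj[remove] = 0
    adj = np.minimum(adj, adj.T)  # removal of (i,j) implies removal of (j,i)
    return Network(list(mi.gene_ids), adj)


def aracne_scores(mi: MIMatrix, eps: float = 0.1) -> ScoredNetwork:
    """MI scores with DPI-pruned pairs zeroed (DPI applied to all pairs).

    Thresholding these scores is the protocol used for the optimal-cutoff
    benchmark: the DPI is run once on the dense matrix and the cutoff
    scan then only thresholds surviving weights.
    """
    adj = (mi.values > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    remove = _dpi_removals(mi.values, adj, eps)
    weights = np.where(remove | (adj == 0), 0.0, mi.values)
    return ScoredNetwork(list(mi.gene_ids), weights)


def clr(mi: MIMatrix) -> ScoredNetwork:
    """Context likelihood of relatedness z-score weights.

    For each gene i with off-diagonal row mean mu_i and standard deviation
    sigma_i, z_i(j) = max(0, (I_ij - mu_i) / sigma_i) and the edge weight
    is sqrt(z_i(j)^2 + z_j(i)^2).
    """
    n = mi.n_genes
    if n < 3:
        raise ValueError("CLR needs at least 3 genes for row statistics")
    off = ~np.eye(n, dtype=bool)
    rows = np.where(off, mi.values, np.nan)
    mu = np.nanmean(rows, axis=1)
    sigma = np.nanstd(rows, axis=1)
    flat = sigma == 0
    if flat.any():
        logger.warning(
            "genes with zero MI-row spread contribute zero z-scores: %s",
            [mi.gene_ids[i] for i in np.flatnonzero(flat)],
        )
    safe_sigma = np.where(flat, 1.0, sigma)
    z = (mi.values - mu[:, None]) / safe_sigma[:, None]
    z = np.clip(z, 0.0, None)
    z[flat, :] = 0.0
    weights = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(weights, 0.0)
    return ScoredNetwork(list(mi.gene_ids), weights)


def mrnet(mi: MIMatrix) -> ScoredNetwork:
    """Maximum-relevance / minimum-redundancy network scores.

    For each target gene t, candidate regulators are added greedily: at
    each step the candidate j maximizing
    s_j = I_jt - mean_{k in selected} I_jk is chosen, its score s_j at
    selection time recorded, and selection stops when the best s_j is
    <= 0.  The undirected weight is the larger of the two directed scores.
    """
    n = mi.n_genes
    directed = np.zeros((n, n))  # directed[j, t] = score of j as regulator of t
    for t in range(n):
        relevance = mi.values[:, t].copy()
        candidates = np.ones(n, dtype=bool)
        candidates[t] = False
        redundancy_sum = np.zeros(n)
        n_selected = 0
        while candidates.any():
            score = relevance.copy()
            if n_selected:
                score = score - redundancy_sum / n_selected
            score[~candidates] = -np.inf
            j = int(np.argmax(score))
            if score[j] <= 0:
                break
            directed[j, t] = score[j]
            candidates[j] = False
            redundancy_sum += mi.values[:, j]
            n_selected += 1
    weights = np.maximum(directed, directed.T)
    np.fill_diagonal(weights, 0.0)
    return ScoredNetwork(list(mi.gene_ids), weights)
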