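"""Scoring inferred networks against a known true network.

The benchmark error measure is the F-score F = 2pr/(p + r) with precision
p = TP/(TP + FP) and recall r = TP/(TP + FN) over undirected edges.  To
assess an inference method independently of any particular threshold, the
optimal cutoff for an edge-score matrix is found by maximizing F over all
candidate thresholds.  Ensemble runs are summarized by the max, min, mean
and median of the per-dataset F-scores, and per-edge recovery frequency
(mean true-positive rate) across an ensemble is reported with the
standard four-color binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MIMatrix, Network, ScoredNetwork

__all__ = [
    "EvalResult",
    "compare_networks",
    "optimal_cutoff",
    "ensemble_summary",
    "edge_tpr",
    "mean_score_per_edge",
]

EdgePair = tuple[int, int]

TPR_BINS = (  # (label, lower-open bound, upper-closed bound); 0.0 itself is red
    ("black", 0.75, 1.0),
    ("blue", 0.5, 0.75),
    ("green", 0.25, 0.5),
    ("red", -1.0, 0.25),
)


@dataclass
class EvalResult:
    """Edge-level confusion counts and derived precision/recall/F-score."""

    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _normalize_mask(mask) -> set[EdgePair] | None:
    if mask is None:
        return None
    return {(min(i, j), max(i, j)) for i, j in mask if i != j}


def compare_networks(
    inferred: Network,
    truth: Network,
    candidate_mask: "set[EdgePair] | None" = None,
) -> EvalResult:
    """Confusion counts of inferred vs true undirected edge sets.

    When ``candidate_mask`` (a set of unordered index pairs) is given,
    both edge sets are restricted to it before counting: inferred edges
    outside the mask are discarded, not counted as false positives.  This
    supports evaluations scored only on eligible pairs, such as a
    regulator x target restriction.
    """
    if inferred.gene_ids != truth.gene_ids:
        missing = sorted(set(inferred.gene_ids) ^ set(truth.gene_ids))
        raise ValueError(f"gene universes differ; mismatched ids: {missing}")
    inf_edges = inferred.edge_indices()
    true_edges = truth.edge_indices()
    mask = _normalize_mask(candidate_mask)
    if mask is not None:
        inf_edges &= mask
        true_edges &= mask
    tp = len(inf_edges & true_edges)
    return EvalResult(TP=tp, FP=len(inf_edges) - tp, FN=len(true_edges) - tp)


def optimal_cutoff(
    scores: "ScoredNetwork | MIMatrix",
    truth: Network,
    candidate_mask: "set[EdgePair] | None" = None,
) -> tuple[float, EvalResult]:
    """Threshold on the edge scores maximizing the F-score against truth.

    All distinct positive score values are scanned as candidate
    thresholds (edges are pairs scoring >= the candidate), plus one
    threshold above the maximum (the empty network).  Ties in F are
    broken toward the smallest threshold, i.e. the densest maximizer.
    Returns the winning threshold and its evaluation.
    """
    if truth.n_edges == 0:
        raise ValueError("true network must be nonempty")
    weights = scores.values if isinstance(scores, MIMatrix) else scores.weights
    if list(scores.gene_ids) != truth.gene_ids:
        raise ValueError("score matrix and truth must share gene ids")
    mask = _normalize_mask(candidate_mask)
    iu = np.triu_indices(truth.n_genes, k=1)
    pair_scores = weights[iu]
    is_true = truth.adjacency[iu].astype(bool)
    if mask is not None:
        keep = np.array([(i, j) in mask for i, j in zip(*iu)])
        pair_scores = pair_scores[keep]
        is_true = is_true[keep]
    n_true = int(is_true.sum())
    if n_true == 0:
        raise ValueError("true network has no edges inside the candidate mask")

    order = np.argsort(-pair_scores, kind="stable")
    sorted_scores = pair_scores[order]
    sorted_true = is_true[order]
    # prefix k = network of the k highest-scoring pairs; only positive scores
    # are ever edges, and equal scores enter together
    tp_cum = np.cumsum(sorted_true)
    ks = np.arange(1, sorted_scores.size + 1)
    last_of_group = np.ones(sorted_scores.size, dtype=bool)
    last_of_group[:-1] = sorted_scores[:-1] != sorted_scores[1:]
    valid = last_of_group & (sorted_scores > 0)

    best_f, best_thr, best_k = 0.0, float(weights.max()) + 1.0, 0
    for idx in np.flatnonzero(valid):
        k = int(ks[idx])
        tp = int(tp_cum[idx])
        fp = k - tp
        fn = n_true - tp
        p = tp / k
        r = tp / n_true
        f = 2 * p * r / (p + r) if p + r else 0.0
        thr = float(sorted_scores[idx])
        if f > best_f or (f == best_f and k > best_k):
            best_f, best_thr, best_k = f, thr, k
    if best_k == 0:
        return best_thr, EvalResult(TP=0, FP=0, FN=n_true)
    tp = int(tp_cum[best_k - 1])
    return best_thr, EvalResult(TP=tp, FP=best_k - tp, FN=n_true - tp)


def ensemble_summary(results: "list[EvalResult] | list[float]") -> dict[str, float]:
    """Max, min, mean and median of an ensemble's F-scores."""
    if not results:
        raise ValueError("empty ensemble")
    fs = np.array([r.fscore if isinstance(r, EvalResult) else float(r) for r in results])
    return {
        "max": float(fs.max()),
        "min": float(fs.min()),
        "mean": float(fs.mean()),
        "median": float(np.median(fs)),
    }


def edge_tpr(
    ensemble_networks: list[Network], truth: Network
) -> dict[EdgePair, tuple[float, str]]:
    """Per-true-edge recovery frequency over an ensemble, with color bin.

    For each true edge, the mean TPR is the fraction of ensemble networks
    containing it.  Bins: black (0.75, 1], blue (0.5, 0.75],
    green (0.25, 0.5], red [0, 0.25].
    """
    if not ensemble_networks:
        raise ValueError("empty ensemble")
    for net in ensemble_networks:
        if net.gene_ids != truth.gene_ids:
            raise ValueError("ensemble networks must share the truth's gene universe")
    out: dict[EdgePair, tuple[float, str]] = {}
    for i, j in sorted(truth.edge_indices()):
        tpr = float(np.mean([net.adjacency[i, j] for net in ensemble_networks]))
        label = next(lbl for lbl, lo, hi in TPR_BINS if lo < tpr <= hi or (tpr == 0.0 and lbl == "red"))
        out[(i, j)] = (tpr, label)
    return out


def mean_score_per_edge(
    scores: "ScoredNetwork | MIMatrix", network: Network
) -> float:
    """Average edge score (MI or z-score) over a network's edges.

    An edge is "significant" exactly when the inference method selected
    it, so this is the mean score per selected edge.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    weights = scores.values if isinstance(scores, MIMatrix) else scores.weights
    if list(scores.gene_ids) != network.gene_ids:
        raise ValueError("score matrix and network must share gene ids")
    vals = [weights[i, j] for i, j in network.edge_indices()]
    return float(np.mean(vals))
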