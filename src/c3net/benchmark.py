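"""Ensemble benchmarking of inference methods against a known truth.

For every dataset of an ensemble, each method's edge-score matrix is
computed from the estimated MI matrix and evaluated at its optimal
cutoff (the threshold maximizing the F-score against the true network),
so methods are compared on their capability rather than on any
particular thresholding rule.  The per-dataset F-scores give the
distribution that the ensemble approach is designed to reveal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import aracne_scores, clr, mrnet
from .containers import ExpressionMatrix, MIMatrix, Network, ScoredNetwork
from .core import c3net_scores
from .evaluation import EvalResult, ensemble_summary, optimal_cutoff
from .mi import mi_matrix

__all__ = ["BenchmarkResult", "method_scores", "benchmark_ensemble", "METHODS"]

METHODS = ("c3net", "rn", "aracne", "clr", "mrnet")


def method_scores(mi: MIMatrix, method: str, eps: float = 0.1) -> ScoredNetwork:
    """The edge-score matrix a method exposes to the cutoff scan.

    RN scores are the MI values themselves; ARACNE's are MI values with
    DPI-pruned pairs zeroed; C3NET's keep only each gene's maximal MI
    entry; CLR and MRNET define their own scores.
    """
    if method == "c3net":
        return c3net_scores(mi)
    if method == "rn":
        return ScoredNetwork(list(mi.gene_ids), mi.values.copy())
    if method == "aracne":
        return aracne_scores(mi, eps=eps)
    if method == "clr":
        return clr(mi)
    if method == "mrnet":
        return mrnet(mi)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


@dataclass
class BenchmarkResult:
    """Per-method optimal-cutoff evaluations over an ensemble."""

    methods: tuple[str, ...]
    results: dict[str, list[EvalResult]] = field(default_factory=dict)
    thresholds: dict[str, list[float]] = field(default_factory=dict)
    networks: dict[str, list[Network]] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        """Max/min/mean/median F-score per method."""
        return {m: ensemble_summary(self.results[m]) for m in self.methods}


def benchmark_ensemble(
    datasets: list[ExpressionMatrix],
    truth: Network,
    methods: "tuple[str, ...] | list[str]" = METHODS,
    estimator: str = "gaussian",
    eps: float = 0.1,
    keep_networks: bool = False,
) -> BenchmarkResult:
    """Evaluate each method at its optimal cutoff on every dataset."""
    methods = tuple(methods)
    out = BenchmarkResult(methods=methods)
    for m in methods:
        out.results[m] = []
        out.thresholds[m] = []
        out.networks[m] = []
    for expr in datasets:
        if expr.gene_ids != truth.gene_ids:
            raise ValueError("dataset gene ids must match the true network")
        mi = mi_matrix(expr, estimator=estimator)
        for m in methods:
            scores = method_scores(mi, m, eps=eps)
            thr, res = optimal_cutoff(scores, truth)
            out.results[m].append(res)
            out.thresholds[m].append(thr)
            if keep_networks:
                # the cutoff scan uses >= on the winning score value
                out.networks[m].append(scores.threshold(np.nextafter(thr, -np.inf)))
    return out
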