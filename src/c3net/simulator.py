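"""Synthetic regulatory networks and steady-state expression ensembles.

The generator emulates the standard synthetic-benchmark protocol for
network inference: sample a subnetwork from a larger source regulatory
topology with the neighbor-addition method, then generate steady-state
expression data through nonlinear Michaelis-Menten / Hill transfer
functions with multiplicative noise.  Ensembles redraw every kinetic
parameter per dataset, emulating biological variability, so a benchmark
yields the distribution of a performance measure rather than one value.

Model
-----
Each directed edge (regulator -> target) is signed.  With regulator
activity x, an activating edge contributes the Hill term
x^h / (K^h + x^h) and a repressing edge K^h / (K^h + x^h); multiple
regulators combine multiplicatively (independent binding).  A target's
expression is b + V * (product of its regulator terms), evaluated in
topological order (models must be acyclic), and root genes draw their
activity uniformly on (0, 1) per sample — the steady-state analogue of
varying experimental conditions.  Multiplicative lognormal noise
exp(N(0, sigma_noise^2)) is applied to every value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .containers import ExpressionMatrix, Network

__all__ = [
    "Edge",
    "RegulatoryModel",
    "KineticRanges",
    "EnsembleSpec",
    "make_source_network",
    "sample_subnetwork",
    "simulate_expression",
    "generate_ensemble",
]

ACTIVATION = +1
REPRESSION = -1


@dataclass(frozen=True)
class Edge:
    """Directed signed regulatory edge with Hill kinetics.

    K is the half-saturation constant (on the unit activity scale) and h
    the Hill coefficient (cooperativity).
    """

    regulator: str
    target: str
    sign: int  # +1 activation, -1 repression
    K: float = 0.5
    h: float = 2.0

    def __post_init__(self):
        if self.regulator == self.target:
            raise ValueError("self-loops are not allowed")
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError("edge sign must be +1 or -1")
        if not (self.K > 0 and np.isfinite(self.K)):
            raise ValueError("K must be positive and finite")
        if not (self.h >= 1 and np.isfinite(self.h)):
            raise ValueError("Hill coefficient must be >= 1")


@dataclass
class RegulatoryModel:
    """Directed, signed regulatory network with per-gene rate parameters.

    ``basal`` (b >= 0) and ``vmax`` (V > 0) give each gene's basal and
    maximal production; ``sigma_noise`` is the lognormal noise parameter.
    """

    gene_ids: list[str]
    edges: list[Edge]
    basal: dict[str, float] = field(default_factory=dict)
    vmax: dict[str, float] = field(default_factory=dict)
    sigma_noise: float = 0.1

    def __post_init__(self):
        ids = set(self.gene_ids)
        if len(ids) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        for e in self.edges:
            if e.regulator not in ids or e.target not in ids:
                raise ValueError(f"edge {e.regulator}->{e.target} references unknown gene")
        for g in self.gene_ids:
            self.basal.setdefault(g, 0.0)
            self.vmax.setdefault(g, 1.0)
            if self.basal[g] < 0:
                raise ValueError("basal level must be >= 0")
            if self.vmax[g] <= 0:
                raise ValueError("max rate must be > 0")
        if self.sigma_noise < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for e in self.edges:
            g.add_edge(e.regulator, e.target, sign=e.sign, K=e.K, h=e.h)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.digraph())

    def true_network(self) -> Network:
        """Undirected view of the true edges, for evaluation."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        pairs = {(index[e.regulator], index[e.target]) for e in self.edges}
        return Network.from_edge_indices(list(self.gene_ids), pairs)


@dataclass(frozen=True)
class KineticRanges:
    """Resampling ranges for kinetic parameters (unit activity scale)."""

    vmax: tuple[float, float] = (0.5, 1.5)
    K: tuple[float, float] = (0.2, 0.8)
    hill: tuple[int, ...] = (1, 2, 3)
    basal: tuple[float, float] = (0.0, 0.05)
    sigma_noise: tuple[float, float] = (0.05, 0.2)


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble layout: N datasets of p samples each, with per-dataset
    kinetic-parameter resampling from ``ranges``."""

    n_datasets: int = 50
    n_samples: int = 200
    ranges: KineticRanges = field(default_factory=KineticRanges)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per dataset")


def make_source_network(
    n_genes: int,
    n_tfs: int,
    rng_seed: int = 0,
    ranges: KineticRanges = KineticRanges(),
) -> RegulatoryModel:
    """Random acyclic scale-free-ish source topology.

    The first ``n_tfs`` genes are transcription factors; every other gene
    attaches to 1-3 TF regulators chosen by preferential attachment
    (probability proportional to current out-degree + 1), which produces
    a right-skewed out-degree distribution with hubs, as in curated
    transcriptional regulatory networks.  TFs beyond the first form a
    sparse regulator hierarchy among earlier TFs, keeping the graph
    acyclic.  Signs are random.  Reproducible per seed.
    """
    if not 1 <= n_tfs < n_genes:
        raise ValueError("need 1 <= n_tfs < n_genes")
    rng = np.random.default_rng(rng_seed)
    width = len(str(n_genes - 1))
    gene_ids = [f"G{str(i).zfill(width)}" for i in range(n_genes)]
    tfs = gene_ids[:n_tfs]
    edges: list[Edge] = []
    out_degree = np.zeros(n_tfs)

    def draw_edge(reg: str, tgt: str) -> Edge:
        return Edge(
            regulator=reg,
            target=tgt,
            sign=ACTIVATION if rng.random() < 0.7 else REPRESSION,
            K=float(rng.uniform(*ranges.K)),
            h=float(rng.choice(ranges.hill)),
        )

    # TF hierarchy: each TF after the first is regulated by an earlier TF,
    # which keeps the source weakly connected (and acyclic by construction)
    for t in range(1, n_tfs):
        r = int(rng.integers(0, t))
        edges.append(draw_edge(tfs[r], tfs[t]))
        out_degree[r] += 1
    # targets attach preferentially to busy TFs
    for tgt in gene_ids[n_tfs:]:
        k = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        probs = (out_degree + 1.0) / (out_degree + 1.0).sum()
        regs = rng.choice(n_tfs, size=min(k, n_tfs), replace=False, p=probs)
        for r in regs:
            edges.append(draw_edge(tfs[int(r)], tgt))
            out_degree[int(r)] += 1
    model = RegulatoryModel(
        gene_ids=gene_ids,
        edges=edges,
        basal={g: float(rng.uniform(*ranges.basal)) for g in gene_ids},
        vmax={g: float(rng.uniform(*ranges.vmax)) for g in gene_ids},
        sigma_noise=float(rng.uniform(*ranges.sigma_noise)),
    )
    assert model.is_acyclic()
    return model


def sample_subnetwork(source: RegulatoryModel, n: int, rng_seed: int = 0) -> RegulatoryModel:
    """Neighbor-addition subnetwork sampling.

    Starting from one random seed node, repeatedly add a uniformly chosen
    node from the undirected neighborhood of the current set until ``n``
    nodes are selected, then return the induced directed subnetwork.  The
    result is connected as an undirected graph.
    """
    if n > source.n_genes:
        raise ValueError("subnetwork larger than source")
    rng = np.random.default_rng(rng_seed)
    g = source.digraph().to_undirected()
    selected = {source.gene_ids[int(rng.integers(source.n_genes))]}
    while len(selected) < n:
        frontier = sorted(
            {nbr for node in selected for nbr in g.neighbors(node)} - selected
        )
        if not frontier:
            raise ValueError(
                "neighborhood exhausted before reaching n nodes "
                "(disconnected source component); try another rng_seed"
            )
        selected.add(frontier[int(rng.integers(len(frontier)))])
    keep = [gid for gid in source.gene_ids if gid in selected]
    kept = set(keep)
    return RegulatoryModel(
        gene_ids=keep,
        edges=[e for e in source.edges if e.regulator in kept and e.target in kept],
        basal={g_: source.basal[g_] for g_ in keep},
        vmax={g_: source.vmax[g_] for g_ in keep},
        sigma_noise=source.sigma_noise,
    )


def _hill(x: np.ndarray, K: float, h: float, sign: int) -> np.ndarray:
    xh = x**h
    kh = K**h
    if sign == ACTIVATION:
        return xh / (kh + xh)
    return kh / (kh + xh)


def simulate_expression(model: RegulatoryModel, p: int, rng_seed: int = 0) -> ExpressionMatrix:
    """Steady-state expression matrix of ``p`` samples from the model.

    Root genes (no regulators) draw activity uniformly on (0, 1) per
    sample; every downstream gene is evaluated in topological order as
    b + V * prod(Hill terms of its regulators), with multiplicative
    lognormal noise exp(N(0, sigma_noise^2)) applied to each computed
    level.  The noisy level is what downstream regulators see, so
    intrinsic variability propagates through cascades and dependence
    decays along indirect paths — without this, a monotone regulatory
    chain would be deterministic end to end and indirect pairs would be
    as dependent as directly interacting ones.  Cyclic models are
    rejected: the closed-form topological evaluation is the only fully
    specified steady state.
    """
    if p < 3:
        raise ValueError("need at least 3 samples")
    dig = model.digraph()
    if not nx.is_directed_acyclic_graph(dig):
        raise ValueError("model contains a cycle; only acyclic models have a closed-form steady state")
    rng = np.random.default_rng(rng_seed)
    index = {g: i for i, g in enumerate(model.gene_ids)}
    values = np.zeros((model.n_genes, p))
    for gene in nx.topological_sort(dig):
        i = index[gene]
        regulators = list(dig.predecessors(gene))
        if not regulators:
            values[i] = rng.uniform(0.0, 1.0, size=p)
            continue
        prod = np.ones(p)
        for reg in regulators:
            attrs = dig.edges[reg, gene]
            prod *= _hill(values[index[reg]], attrs["K"], attrs["h"], attrs["sign"])
        level = model.basal[gene] + model.vmax[gene] * prod
        if model.sigma_noise > 0:
            level = level * np.exp(rng.normal(0.0, model.sigma_noise, size=p))
        values[i] = level
    # strictly positive floor: a zero basal with zero Hill product can hit 0
    values = np.maximum(values, 1e-12)
    return ExpressionMatrix(list(model.gene_ids), values)


def _resample_parameters(
    model: RegulatoryModel, ranges: KineticRanges, rng: np.random.Generator
) -> RegulatoryModel:
    edges = [
        replace(
            e,
            K=float(rng.uniform(*ranges.K)),
            h=float(rng.choice(ranges.hill)),
        )
        for e in model.edges
    ]
    return RegulatoryModel(
        gene_ids=list(model.gene_ids),
        edges=edges,
        basal={g: float(rng.uniform(*ranges.basal)) for g in model.gene_ids},
        vmax={g: float(rng.uniform(*ranges.vmax)) for g in model.gene_ids},
        sigma_noise=float(rng.uniform(*ranges.sigma_noise)),
    )


def generate_ensemble(model: RegulatoryModel, spec: EnsembleSpec) -> list[ExpressionMatrix]:
    """N expression datasets with kinetic parameters redrawn per dataset.

    Dataset seeds derive deterministically from ``spec.rng_seed``, so the
    whole ensemble is reproducible from the spec alone.
    """
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(spec.n_datasets)
    datasets = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        redrawn = _resample_parameters(model, spec.ranges, rng)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        datasets.append(simulate_expression(redrawn, spec.n_samples, rng_seed=sim_seed))
    return datasets
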