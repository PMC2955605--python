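"""Reading and writing expression tables, MI matrices and networks.

Expression tables are TSV/CSV with gene ids in the first column and a
header row of sample ids (genes in rows by default — the microarray
convention — with a transpose flag for samples-in-rows dialects).
Networks are written as sorted unordered pairs: plain edge lists, SIF
("gene1 mi gene2") or a square adjacency table.  Regulatory models round
trip through 3-column signed edge lists.  All writers are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MIMatrix, Network, ScoredNetwork
from .simulator import Edge, RegulatoryModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_mi_matrix",
    "write_mi_matrix",
    "write_network",
    "read_network",
    "write_regulatory_model",
    "read_regulatory_model",
    "write_ensemble",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, samples_in_rows: bool = False, sep: str | None = None
) -> ExpressionMatrix:
    """Read an expression table; first column ids, header of sample ids.

    Raises descriptive errors on duplicate gene ids, non-numeric cells or
    ragged rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if samples_in_rows:
        df = df.T
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene ids: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = [
            f"row {i + 2} ({df.index[i]})"
            for i in range(len(df))
            if pd.to_numeric(df.iloc[i], errors="coerce").isna().any()
        ]
        raise ValueError(f"{path}: non-numeric cells in {bad}") from exc
    return ExpressionMatrix([str(g) for g in df.index], values)


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        expr.values,
        index=expr.gene_ids,
        columns=[f"S{i + 1}" for i in range(expr.n_samples)],
    )
    df.to_csv(path, sep=_sep_for(path, sep), index_label="gene")


def write_mi_matrix(mi: MIMatrix, path: str | Path) -> None:
    """Square TSV of MI values with gene ids on both axes, full precision."""
    df = pd.DataFrame(mi.values, index=mi.gene_ids, columns=mi.gene_ids)
    df.to_csv(Path(path), sep="\t", index_label="gene", float_format="%.17g")


def read_mi_matrix(path: str | Path, units: str = "nats") -> MIMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    return MIMatrix([str(g) for g in df.index], df.to_numpy(dtype=float), units=units)


def write_network(
    net: "Network | ScoredNetwork", path: str | Path, format: str = "edgelist"
) -> None:
    """Write a network: each undirected edge once, lexicographic order.

    Formats: ``edgelist`` (two tab-separated gene columns, plus a weight
    column for scored networks), ``sif`` (interaction label "mi"), or
    ``adjacency`` (square table).  Byte output is deterministic.
    """
    path = Path(path)
    if format not in ("edgelist", "sif", "adjacency"):
        raise ValueError(f"unknown format {format!r}")
    if format == "adjacency":
        values = net.adjacency if isinstance(net, Network) else net.weights
        pd.DataFrame(values, index=net.gene_ids, columns=net.gene_ids).to_csv(
            path, sep="\t", index_label="gene"
        )
        return
    if isinstance(net, ScoredNetwork):
        ii, jj = np.nonzero(np.triu(net.weights, k=1))
        rows = sorted(
            (*sorted((net.gene_ids[i], net.gene_ids[j])), net.weights[i, j])
            for i, j in zip(ii.tolist(), jj.tolist())
        )
    else:
        rows = [(a, b) for a, b in net.edges()]
    with open(path, "w") as fh:
        for row in rows:
            if format == "sif":
                fh.write(f"{row[0]}\tmi\t{row[1]}\n")
            elif len(row) == 3:
                fh.write(f"{row[0]}\t{row[1]}\t{row[2]:.17g}\n")
            else:
                fh.write(f"{row[0]}\t{row[1]}\n")


def read_network(
    path: str | Path, gene_ids: list[str] | None = None, format: str = "edgelist"
) -> Network:
    """Read an edge list or SIF file into a network.

    ``gene_ids`` fixes the gene universe (needed to represent isolated
    genes); when omitted, the sorted set of ids seen in the file is used.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if format == "sif":
                a, b = parts[0], parts[2]
            else:
                a, b = parts[0], parts[1]
            pairs.append((a, b))
    if gene_ids is None:
        gene_ids = sorted({g for p in pairs for g in p})
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = sorted({g for p in pairs for g in p} - set(index))
    if missing:
        raise ValueError(f"{path}: ids outside the gene universe: {missing}")
    return Network.from_edge_indices(gene_ids, [(index[a], index[b]) for a, b in pairs])


def write_regulatory_model(model: RegulatoryModel, path: str | Path, format: str = "edgelist") -> None:
    """Directed signed edge list (regulator, target, sign) or SIF
    (labels "activates"/"represses"); gene-level parameters to a JSON
    sidecar next to the edge file."""
    path = Path(path)
    with open(path, "w") as fh:
        for e in sorted(model.edges, key=lambda e: (e.regulator, e.target)):
            if format == "sif":
                label = "activates" if e.sign > 0 else "represses"
                fh.write(f"{e.regulator}\t{label}\t{e.target}\n")
            else:
                fh.write(f"{e.regulator}\t{e.target}\t{e.sign:+d}\n")
    params = {
        "gene_ids": model.gene_ids,
        "basal": model.basal,
        "vmax": model.vmax,
        "sigma_noise": model.sigma_noise,
        "edge_kinetics": {
            f"{e.regulator}->{e.target}": {"K": e.K, "h": e.h} for e in model.edges
        },
    }
    path.with_suffix(path.suffix + ".params.json").write_text(json.dumps(params, indent=1))


def read_regulatory_model(path: str | Path) -> RegulatoryModel:
    path = Path(path)
    params_path = path.with_suffix(path.suffix + ".params.json")
    params = json.loads(params_path.read_text()) if params_path.exists() else None
    edges = []
    seen: set[str] = set()
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if parts[1] in ("activates", "represses"):
                reg, tgt = parts[0], parts[2]
                sign = 1 if parts[1] == "activates" else -1
            else:
                reg, tgt, sign = parts[0], parts[1], int(parts[2])
            kin = {}
            if params:
                kin = params["edge_kinetics"].get(f"{reg}->{tgt}", {})
            edges.append(Edge(reg, tgt, sign, K=kin.get("K", 0.5), h=kin.get("h", 2.0)))
            for g in (reg, tgt):
                if g not in seen:
                    seen.add(g)
                    order.append(g)
    if params:
        return RegulatoryModel(
            gene_ids=params["gene_ids"],
            edges=edges,
            basal=dict(params["basal"]),
            vmax=dict(params["vmax"]),
            sigma_noise=params["sigma_noise"],
        )
    return RegulatoryModel(gene_ids=order, edges=edges)


def write_ensemble(
    datasets: list[ExpressionMatrix], outdir: str | Path, manifest: dict | None = None
) -> list[Path]:
    """Numbered expression TSVs plus a JSON manifest of the run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, expr in enumerate(datasets):
        p = outdir / f"dataset_{k:03d}.tsv"
        write_expression(expr, p)
        paths.append(p)
    info = dict(manifest or {})
    info["n_datasets"] = len(datasets)
    info["files"] = [p.name for p in paths]
    (outdir / "manifest.json").write_text(json.dumps(info, indent=1))
    return paths
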