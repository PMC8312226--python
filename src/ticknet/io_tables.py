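"""Readers and writers for the pipeline's interchange formats.

Formats: TSV count tables (taxa as rows, samples as columns; lines beginning
with ``#`` are schema comments), a minimal BIOM-style JSON dialect
(rows/columns/data triplets), Newick trees, GEXF networks, and TSV/JSON
result tables. Every TSV written here starts with a ``#`` comment naming its
columns so outputs are self-describing and re-readable by the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from .compnet import CorrelationModel, SignedNetwork
from .containers import CountTable, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "write_network_gexf",
    "read_network_gexf",
    "write_edge_list",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_json",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_counts(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a taxa x samples count table from TSV or BIOM-style JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = _read_tsv(path)
        except Exception as exc:  # malformed header/body
            raise ValidationError(f"cannot parse count TSV {path}: {exc}") from exc
        return CountTable(df)
    if format == "biom_json":
        payload = json.loads(path.read_text())
        for key in ("rows", "columns", "data", "shape"):
            if key not in payload:
                raise ValidationError(f"BIOM JSON missing key {key!r}")
        n_rows, n_cols = payload["shape"]
        arr = np.zeros((n_rows, n_cols))
        if payload.get("matrix_type", "sparse") == "dense":
            arr[:] = np.asarray(payload["data"], float)
        else:
            for i, j, v in payload["data"]:
                arr[int(i), int(j)] = v
        df = pd.DataFrame(
            arr,
            index=[r["id"] for r in payload["rows"]],
            columns=[c["id"] for c in payload["columns"]],
        )
        return CountTable(df)
    raise ValidationError(f"unknown counts format {format!r}")


def write_counts(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# counts: taxa as rows, samples as columns\n")
        table.counts.rename_axis("taxon").to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample metadata: columns {list(meta.columns)}\n")
        meta.to_csv(fh, sep="\t")


def read_newick(path: str | Path) -> skbio.TreeNode:
    try:
        return skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_network_gexf(net: SignedNetwork, path: str | Path) -> None:
    """GEXF export with node abundance/ubiquity/centrality and signed weights."""
    from .topology import eigenvector_centrality

    g = net.graph.copy()
    if g.number_of_edges():
        cent = eigenvector_centrality(net)
        nx.set_node_attributes(g, {n: float(cent[n]) for n in g.nodes}, "centrality")
    nx.write_gexf(g, str(path))


def read_network_gexf(path: str | Path, r_min: float = 0.0, alpha: float = 1.0) -> SignedNetwork:
    g = nx.read_gexf(str(path))
    return SignedNetwork(graph=nx.Graph(g), r_min=r_min, alpha=alpha)


def write_edge_list(net: SignedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# edges: taxon_a, taxon_b, weight, sign, p, padj\n")
        fh.write("taxon_a\ttaxon_b\tweight\tsign\tp\tpadj\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{d['weight']:.6g}\t{d['sign']}\t{d.get('p', float('nan')):.6g}"
                f"\t{d.get('padj', float('nan')):.6g}\n"
            )


def write_matrix_tsv(matrix: np.ndarray | pd.DataFrame, ids, path: str | Path,
                     comment: str = "square matrix") -> None:
    df = pd.DataFrame(np.asarray(matrix), index=ids, columns=ids)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_correlation_model(model: CorrelationModel, outdir: str | Path, prefix: str = "sparcc") -> None:
    outdir = Path(outdir)
    write_matrix_tsv(model.rho, model.taxa, outdir / f"{prefix}_rho.tsv",
                     "basis correlations rho_ij")
    if model.pvals is not None:
        write_matrix_tsv(model.pvals, model.taxa, outdir / f"{prefix}_pvals.tsv",
                         "two-sided permutation pseudo-p-values")
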