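"""Tabular and GraphML input/output with strict validation."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "read_abundance",
    "read_metadata",
    "read_taxonomy",
    "write_edge_list",
    "write_graphml",
    "read_graphml",
]


def read_abundance(path) -> pd.DataFrame:
    """Read a features x samples abundance TSV (first column = feature id).

    Duplicate feature ids, missing cells, and non-numeric cells are
    rejected with the offending row/column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicate feature id(s): {dupes}")
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        bad = out.index[out[col].isna()][0]
        # +2: header line plus 1-based numbering
        line = int(np.where(df.index == bad)[0][0]) + 2
        raise ValueError(
            f"{path.name}: non-numeric or missing cell at row {line} "
            f"(feature {bad!r}), column {col!r}"
        )
    out.index = out.index.astype(str)
    return out


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with at least (sample, stage) columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "stage"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    return df.set_index("sample")


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV: (taxon, lineage, beneficial 0/1)."""
    df = pd.read_csv(path, sep="\t")
    if "taxon" not in df.columns or "beneficial" not in df.columns:
        raise ValueError("taxonomy needs 'taxon' and 'beneficial' columns")
    df = df.set_index("taxon")
    df["beneficial"] = df["beneficial"].astype(bool)
    return df


def write_edge_list(network: nx.Graph, path) -> None:
    """Edge TSV (taxon_a, taxon_b, r, p, q, stage) sorted by pair id."""
    stage = network.graph.get("stage", "")
    rows = [
        {
            "taxon_a": min(a, b),
            "taxon_b": max(a, b),
            "r": d.get("r"),
            "p": d.get("p"),
            "q": d.get("q"),
            "stage": stage,
        }
        for a, b, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "q", "stage"]).sort_values(
        ["taxon_a", "taxon_b"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.Graph, path) -> None:
    """GraphML with a per-edge sign attribute added for viewer styling."""
    g = network.copy()
    for _, _, d in g.edges(data=True):
        d["sign"] = "positive" if d.get("r", 0.0) >= 0 else "negative"
        for k, v in list(d.items()):
            if isinstance(v, float) and np.isnan(v):
                del d[k]
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
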