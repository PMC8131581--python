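"""Readers and writers for the pipeline's tabular and graph formats.

TSV is the canonical dialect; ``#``-prefixed lines are comments. Readers
validate shape and content up front and fail with the offending row/column
named — silently truncated files are rejected, never padded.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

CONDITIONS = ("ctrl", "CB", "AML")
METADATA_COLUMNS = ("sample_id", "stromal_type", "condition", "replicate")

_FLOAT_FORMAT = "%.10g"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column is the gene id."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: counts file needs a gene column plus >=1 sample")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    df = df.set_index(gene_col)
    df.index.name = "gene"
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ValueError(
                f"{path}: non-numeric or missing count at gene {row!r}, sample {col!r}"
            )
        if (numeric < 0).any():
            row = df.index[(numeric < 0)][0]
            raise ValueError(f"{path}: negative count at gene {row!r}, sample {col!r}")
        frac = numeric % 1
        if (frac != 0).any():
            row = df.index[(frac != 0)][0]
            raise ValueError(
                f"{path}: non-integer count at gene {row!r}, sample {col!r}"
            )
        df[col] = numeric.astype(np.int64)
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if meta.isna().any().any():
        row = int(np.where(meta.isna().any(axis=1))[0][0])
        raise ValueError(f"{path}: missing value in metadata row {row}")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(
            f"{path}: unknown condition values {sorted(bad)}; expected one of {CONDITIONS}"
        )
    meta["replicate"] = meta["replicate"].astype(int)
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Generic feature x sample real-valued matrix."""
    df = _read_tsv(path, index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing or non-rectangular value in row {row!r}")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    expr.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FORMAT)


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    pairs = _read_tsv(path)
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValueError(f"{path}: pair table missing column {col!r}")
    if "pathway" not in pairs.columns:
        pairs["pathway"] = None
    pairs["ligand"] = pairs["ligand"].astype(str).str.strip().str.upper()
    pairs["receptor"] = pairs["receptor"].astype(str).str.strip().str.upper()
    dup = pairs.duplicated(subset=["ligand", "receptor"])
    if dup.any():
        lig, rec = pairs.loc[dup, ["ligand", "receptor"]].iloc[0]
        raise ValueError(f"{path}: duplicate ligand-receptor pair ({lig}, {rec})")
    return pairs[["ligand", "receptor", "pathway"]]


def write_lr_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Symbols are uppercased; empty sets are rejected.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column protein-name to gene-symbol translation table."""
    df = _read_tsv(path, header=None, names=["protein", "gene"])
    return {
        str(p).strip().upper(): str(g).strip().upper()
        for p, g in zip(df["protein"], df["gene"])
    }


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    required = {"feature", "log2FC", "p", "padj", "call"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return table


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV (``.tsv``) or GraphML (``.graphml``), by extension."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
        return
    rows = [
        (u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )


def read_graph_edgelist(path: str | Path) -> nx.Graph:
    df = _read_tsv(path)
    graph = nx.Graph()
    for _, row in df.iterrows():
        graph.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return graph
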