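"""Ligand-receptor integration of secretome and transcriptome calls.

Joins significant secretome proteins (ligands) with significant genes
(receptors) per stromal type through a ligand-receptor pair table, flags
directional coherence, and collapses the result into a weighted bipartite
graph of stromal types versus pathways or pairs.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "stromal_type",
    "ligand",
    "ligand_dir",
    "receptor",
    "receptor_dir",
    "coherent",
    "pathway",
]


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _significant_directions(de: pd.DataFrame) -> dict[str, str]:
    sig = de.loc[de["call"].isin(["up", "down"])]
    return {normalize_symbol(f): c for f, c in zip(sig["feature"], sig["call"])}


def build_edges(
    secretome_de: pd.DataFrame,
    stromal_de: dict[str, pd.DataFrame],
    pairs: pd.DataFrame,
    protein_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Emit one edge per (stromal type, L-R pair) with both calls significant.

    Ligands are significant secretome proteins, receptors significant genes
    in that stromal type; the coherence flag records whether the two
    directions agree. Symbols are matched after normalization (and optional
    protein-to-gene mapping of ligand names). Unmatched symbols are logged,
    not fatal.
    """
    if pairs.empty:
        raise ValueError("ligand-receptor pair table is empty")
    mapping = {normalize_symbol(k): normalize_symbol(v) for k, v in (protein_to_gene or {}).items()}
    ligand_dir = _significant_directions(secretome_de)
    has_pathway = "pathway" in pairs.columns

    pair_rows = []
    seen: set[tuple[str, str]] = set()
    for _, row in pairs.iterrows():
        lig = normalize_symbol(row["ligand"])
        lig = mapping.get(lig, lig)
        rec = normalize_symbol(row["receptor"])
        key = (lig, rec)
        if key in seen:
            continue
        seen.add(key)
        pw = row["pathway"] if has_pathway and pd.notna(row.get("pathway")) else None
        pair_rows.append((lig, rec, pw))

    known_ligands = set(ligand_dir)
    unmatched = {lig for lig, _, _ in pair_rows} - {
        normalize_symbol(f) for f in secretome_de["feature"]
    }
    if unmatched:
        logger.info("%d ligand symbols not present in the secretome table", len(unmatched))

    edges = []
    for stype, de in stromal_de.items():
        receptor_dir = _significant_directions(de)
        for lig, rec, pw in pair_rows:
            if lig in known_ligands and rec in receptor_dir:
                ld, rd = ligand_dir[lig], receptor_dir[rec]
                edges.append((stype, lig, ld, rec, rd, ld == rd, pw))
    return pd.DataFrame(edges, columns=EDGE_COLUMNS)


def coherence_filter(edges: pd.DataFrame) -> pd.DataFrame:
    """Retain edges whose ligand and receptor move in the same direction."""
    return edges.loc[edges["coherent"]].reset_index(drop=True)


def build_graph(edges: pd.DataFrame, group_by: str = "pathway") -> nx.Graph:
    """Collapse edges into a weighted bipartite graph.

    Node set = stromal types plus grouping units (pathways, or L-R pairs
    when ``group_by='pair'`` or pathway labels are absent); edge weight =
    number of collapsed interaction records; node attribute
    ``n_connections`` is the weighted degree used for size scaling.
    """
    if edges.empty:
        raise ValueError("no edges to build a graph from")
    if group_by not in {"pathway", "pair"}:
        raise ValueError("group_by must be 'pathway' or 'pair'")
    if group_by == "pathway" and edges["pathway"].isna().all():
        group_by = "pair"

    graph = nx.Graph()
    for _, row in edges.iterrows():
        stype = row["stromal_type"]
        if group_by == "pathway":
            unit = row["pathway"]
            if pd.isna(unit) or unit is None:
                unit = f"{row['ligand']}->{row['receptor']}"
        else:
            unit = f"{row['ligand']}->{row['receptor']}"
        graph.add_node(stype, bipartite=0, kind="stromal_type")
        graph.add_node(unit, bipartite=1, kind=group_by)
        if graph.has_edge(stype, unit):
            graph[stype][unit]["weight"] += 1
        else:
            graph.add_edge(stype, unit, weight=1)
    for node in graph.nodes:
        graph.nodes[node]["n_connections"] = int(
            sum(d["weight"] for _, _, d in graph.edges(node, data=True))
        )
    return graph


def pair_recovery(
    edges: pd.DataFrame, truth_pairs: set[tuple[str, str, str, str]]
) -> tuple[float, float]:
    """Precision and recall of coherent edges against planted truth records
    ``(ligand, receptor, stromal_type, direction)``."""
    found = {
        (r["ligand"], r["receptor"], r["stromal_type"], r["ligand_dir"])
        for _, r in coherence_filter(edges).iterrows()
    }
    if not found:
        return 0.0, 0.0
    tp = len(found & truth_pairs)
    precision = tp / len(found)
    recall = tp / len(truth_pairs) if truth_pairs else 1.0
    return precision, recall
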