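"""End-to-end orchestration of the analysis stages.

``run_all`` drives simulate -> normalize -> DE -> cluster -> patterns ->
secretome -> interactome -> layout on synthetic inputs and writes every
intermediate as TSV (plus GraphML and layout coordinates) under an output
directory. All randomness derives from one seed, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from nicheomics import clustering, de, interactome, io, layout, normalization
from nicheomics import patterns as patterns_mod
from nicheomics import secretome as secretome_mod
from nicheomics.simulate import GroundTruth, SimulationConfig, simulate_counts, simulate_secretome

logger = logging.getLogger(__name__)


def simulate_inputs(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate and write all pipeline inputs plus a ground-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = simulate_counts(cfg)
    intens, sec_meta, lr, truth = simulate_secretome(cfg, truth)
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_metadata(meta, outdir / "metadata.tsv")
    io.write_expression(intens, outdir / "secretome.tsv", index_label="protein")
    io.write_metadata(sec_meta, outdir / "secretome_metadata.tsv")
    io.write_lr_pairs(lr, outdir / "lr_pairs.tsv")
    truth_rows = [
        {
            "gene": g,
            "cluster": truth.cluster_of_gene[g],
            "pattern": "".join(f"{v:+d}"[0] if v else "0" for v in truth.pattern_of_gene[g]),
        }
        for g in counts.index
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return counts, meta, intens, sec_meta, lr, truth


def run_all(
    outdir: str | Path,
    seed: int = 0,
    fdr: float = 0.1,
    config_overrides: dict | None = None,
) -> dict:
    """Run the full pipeline on synthetic data and write all outputs.

    Returns a manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(config_overrides or {})
    overrides["seed"] = seed
    cfg = SimulationConfig(**overrides)

    inputs_dir = outdir / "inputs"
    counts, meta, intens, sec_meta, lr, truth = simulate_inputs(cfg, inputs_dir)

    # normalization
    factors = normalization.size_factors(counts)
    expr = normalization.regularized_log(counts, factors)
    zprof, flat = normalization.z_profiles(expr, meta, condition="ctrl")
    corr = normalization.sample_correlation(expr)
    factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample_id")
    io.write_expression(expr, outdir / "normexpr.tsv", index_label="gene")
    io.write_expression(zprof, outdir / "zprofiles.tsv", index_label="gene")
    io.write_expression(corr, outdir / "sample_correlation.tsv", index_label="sample_id")

    # differential expression
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    stromal_de = de.per_stromal_de(counts, factors, meta, ("AML", "ctrl"), q=fdr)
    for stype, table in stromal_de.items():
        io.write_de_table(table, de_dir / f"AML_vs_ctrl_{stype}.tsv")
    pairwise = de.pairwise_stromal_de(counts, factors, meta, condition="ctrl", q=0.05)
    for (a, b), table in pairwise.items():
        io.write_de_table(table, de_dir / f"ctrl_{a}_vs_{b}.tsv")
    stromal_types = list(dict.fromkeys(meta["stromal_type"]))
    selected = de.select_cluster_genes(pairwise, stromal_types, threshold=0.05)

    # density-peak clustering of selected, non-flat genes
    cluster_genes = sorted(selected - set(zprof.index[flat]))
    clusters_dir = outdir / "clusters"
    clusters_dir.mkdir(exist_ok=True)
    n_clusters_found = 0
    if len(cluster_genes) > max(2, cfg.n_clusters):
        sub = zprof.loc[cluster_genes]
        stats = clustering.density_stats(sub, d_c="auto")
        assign = clustering.assign_clusters(stats, k=cfg.n_clusters)
        assign = clustering.exclude_halo(assign, stats, sub)
        summary, mean_profiles = clustering.compactness(assign, sub)
        stats_out = stats.drop(columns="nearest_higher")
        io.write_expression(stats_out, clusters_dir / "decision_graph.tsv", index_label="gene")
        assign.to_csv(clusters_dir / "assignments.tsv", sep="\t", index_label="gene")
        summary.to_csv(clusters_dir / "summary.tsv", sep="\t", index=False, float_format="%.10g")
        io.write_expression(mean_profiles, clusters_dir / "mean_profiles.tsv", index_label="cluster")
        shift = clustering.cluster_condition_shift(
            {c: g.index.tolist() for c, g in assign.loc[~assign["is_halo"]].groupby("cluster")},
            stromal_de,
            q=fdr,
        )
        shift.to_csv(clusters_dir / "condition_shift.tsv", sep="\t", index=False, float_format="%.10g")
        n_clusters_found = int(assign["cluster"].nunique())
    else:
        logger.warning("too few selected genes (%d) for clustering", len(cluster_genes))

    # deregulation patterns
    ternary = patterns_mod.ternarize(stromal_de, q=fdr, stromal_types=stromal_types)
    dereg = ternary.loc[(ternary != 0).any(axis=1)]
    if len(dereg) >= 2:
        model = patterns_mod.fit_pattern_model(
            dereg, m_max=min(10, len(dereg)), seed=seed
        )
        model.patterns.to_csv(outdir / "patterns.tsv", sep="\t", index_label="pattern")
        sharing = patterns_mod.pattern_sharing(model)
        sharing.to_csv(outdir / "pattern_sharing.tsv", sep="\t", index=False)
        model.assignment.to_frame().to_csv(
            outdir / "pattern_assignments.tsv", sep="\t", index_label="gene"
        )
        eps_fitted = model.eps
    else:
        logger.warning("no deregulated genes; skipping pattern model")
        eps_fitted = None

    # secretome
    qn = secretome_mod.quantile_normalize(intens)
    log_qn = secretome_mod.log2_transform(qn)
    sec_de = secretome_mod.moderated_t(log_qn, sec_meta, ("AML", "ctrl"), q=fdr)
    io.write_de_table(sec_de, outdir / "secretome_de.tsv")

    # interactome + layout
    edges = interactome.build_edges(sec_de, stromal_de, lr)
    coherent = interactome.coherence_filter(edges)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    n_coherent = len(coherent)
    if n_coherent:
        graph = interactome.build_graph(coherent, group_by="pathway")
        io.write_graph(graph, outdir / "graph.graphml")
        io.write_graph(graph, outdir / "graph_edges.tsv")
        coords = layout.layout(graph, layout.LayoutParams(seed=seed))
        coords["converged"] = bool(coords.attrs["converged"])
        coords.to_csv(outdir / "layout.tsv", sep="\t", index=False, float_format="%.10g")
    else:
        logger.warning("no coherent edges; skipping graph and layout")

    manifest = {
        "seed": seed,
        "fdr": fdr,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "n_selected_genes": len(selected),
        "n_clusters_found": n_clusters_found,
        "n_deregulated_genes": int((ternary != 0).any(axis=1).sum()),
        "pattern_eps": eps_fitted,
        "n_secretome_hits": int((sec_de["call"] != "ns").sum()),
        "n_edges": len(edges),
        "n_coherent_edges": n_coherent,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
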