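"""Pipeline orchestration and figure-style outputs.

``run_pipeline`` executes the three analysis strategies end to end on the
tabular inputs: (1) all-gene embedding + DBSCAN/Dunn, (2) DE + modules +
enrichment, (3) GO-filtered embeddings and designer indicator panels,
plus the congener-contamination check when a marker table is supplied.
Heatmaps order genes by average-linkage hierarchical clustering of their
z-score rows and columns by experimental group.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from . import de as de_mod
from . import expression as expr_mod
from . import network as net_mod
from . import panel as panel_mod
from . import phenotype as phen_mod
from . import species as species_mod
from .ontology import (OntologyGraph, fisher_enrichment, go_filter_transcripts,
                       parse_obo, write_enrichment)

log = logging.getLogger("diapausetx")


def order_columns_by_group(sample_ids: Sequence[str], samples: pd.DataFrame) -> list[str]:
    order = {g: i for i, g in enumerate(expr_mod.GROUP_ORDER)}
    return sorted(sample_ids, key=lambda s: (order.get(samples.loc[s, "group"], 99), s))


def render_heatmap(
    z: expr_mod.ExpressionMatrix,
    gene_ids: Sequence[str],
    samples: pd.DataFrame,
    out_tsv: str | Path,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Clustered z-score heatmap; the row-ordered matrix is written as TSV
    so the ordering itself is testable.  Rows: average-linkage on Euclidean
    distance; columns: group order EF, LF, EC, LC."""
    gene_ids = list(gene_ids)
    if len(gene_ids) < 2:
        raise ValueError("heatmap needs at least 2 genes")
    missing = [g for g in gene_ids if g not in z.values.index]
    if missing:
        raise KeyError(f"genes missing from matrix: {missing[:5]}")
    sub = z.values.loc[gene_ids]
    link = average(pdist(sub.to_numpy(dtype=float)))
    row_order = [gene_ids[i] for i in leaves_list(link)]
    cols = order_columns_by_group(sub.columns, samples)
    ordered = sub.loc[row_order, cols]
    ordered.to_csv(out_tsv, sep="\t", index_label="transcript_id")
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, max(3, len(row_order) * 0.06)))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-2.5, vmax=2.5)
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label="z-score")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return ordered


@dataclass
class PipelineConfig:
    counts_path: str
    catalog_path: str
    samples_path: str
    obo_path: str | None = None
    markers_path: str | None = None
    outdir: str = "results/run"
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_cpm_samples: int = 4
    perplexity: float = 5.0
    iterations: int = 50_000
    repeats: int = 10
    min_pts: int = 3
    network_beta: int = 14
    min_module_size: int = 100
    go_filter_terms: tuple[str, ...] = ("GO:0048477", "GO:0006633", "GO:0016070")
    deg_definition: str = "global"
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _write_embedding(result: phen_mod.EmbeddingResult, outdir: Path, name: str) -> dict:
    table = result.coordinates.copy()
    table["cluster"] = result.labels
    table.to_csv(outdir / f"embedding_{name}.tsv", sep="\t", index_label="sample_id")
    diag = {
        "eps": result.eps,
        "dunn": result.dunn,
        "n_clusters": result.n_clusters,
        "n_noise": result.n_noise,
        "kl_per_repeat": list(result.kl_per_repeat),
        "stability": result.stability,
        "perplexity": result.perplexity,
        "iterations": result.iterations,
        "seed": result.seed,
    }
    (outdir / f"embedding_{name}.json").write_text(json.dumps(diag, indent=1))
    return diag


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dict (also written
    to the output directory).  Deterministic given fixed inputs and seeds."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "outputs": [], "stages": {}}

    counts, catalog, samples = expr_mod.read_counts(
        config.counts_path, config.catalog_path, config.samples_path
    )
    log.info("inputs: counts %s, catalog %s, samples %s",
             counts.shape, catalog.shape, samples.shape)
    ladder = expr_mod.normalization_ladder(counts, catalog)
    for stage, mat in ladder.items():
        path = outdir / f"expression_{stage}.tsv"
        expr_mod.write_expression(mat, path)
        manifest["outputs"].append(path.name)
    log2 = ladder["log2rpkm"]
    z = ladder["zscore"]

    graph: OntologyGraph | None = None
    annotation: dict[str, frozenset] | None = None
    if config.obo_path:
        graph = parse_obo(config.obo_path)
        annotation = {t: catalog.loc[t, "go_terms"] for t in catalog.index
                      if catalog.loc[t, "go_terms"]}

    # strategy 1: all-gene embedding
    all_genes = phen_mod.phenotype_pipeline(
        log2, samples=samples, perplexity=config.perplexity,
        iterations=config.iterations, repeats=config.repeats,
        min_pts=config.min_pts, seed=config.seed,
    )
    manifest["stages"]["all_gene_embedding"] = _write_embedding(all_genes, outdir, "all_genes")

    # strategy 2: DE + modules (+ enrichment when an ontology is supplied)
    results, degs = de_mod.run_de(
        counts, samples, alpha=config.alpha, min_cpm=config.min_cpm,
        min_samples=config.min_cpm_samples, deg_definition=config.deg_definition,
    )
    de_summary = {}
    for label, res in results.items():
        de_mod.write_de_table(res, outdir / f"de_{label}.tsv")
        manifest["outputs"].append(f"de_{label}.tsv")
        sig = res.table["fdr"] <= config.alpha
        de_summary[label] = {
            "degs": int(sig.sum()),
            "up": int((sig & (res.table["direction"] == "up")).sum()),
            "down": int((sig & (res.table["direction"] == "down")).sum()),
        }
    manifest["stages"]["de"] = de_summary
    manifest["stages"]["deg_count"] = len(degs)

    module_labels = None
    if len(degs) >= 3:
        deg_log2 = log2.subset(sorted(degs))
        tom = net_mod.tom_similarity(deg_log2, beta=config.network_beta)
        module_labels = net_mod.detect_modules(
            tom, min_size=min(config.min_module_size, max(2, tom.shape[0] // 4)),
            expr=deg_log2,
        )
        module_labels.to_frame().to_csv(outdir / "modules.tsv", sep="\t",
                                        index_label="transcript_id")
        if (module_labels != net_mod.UNASSIGNED).any():
            eig, var = net_mod.module_eigengenes(deg_log2, module_labels)
            eig.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
            corr, pvals = net_mod.module_trait_correlation(eig, samples)
            corr.to_csv(outdir / "module_trait_r.tsv", sep="\t", index_label="module")
            pvals.to_csv(outdir / "module_trait_p.tsv", sep="\t", index_label="module")
            net_mod.eigengene_group_summaries(eig, samples).to_csv(
                outdir / "eigengene_boxplots.tsv", sep="\t", index=False)
        manifest["stages"]["modules"] = module_labels.value_counts().to_dict()

    if graph is not None and annotation is not None and len(degs) >= 1:
        universe = [t for t in counts.index if annotation.get(t)]
        study = [t for t in degs if t in set(universe)]
        if study:
            table = fisher_enrichment(study, universe, annotation, graph,
                                      alpha=config.alpha)
            write_enrichment(table, outdir / "enrichment_degs.tsv")
            manifest["stages"]["enrichment"] = int(table["enriched"].sum())

    # strategy 3: GO-filtered embeddings + designer panels
    if graph is not None and annotation is not None:
        filter_summaries = {}
        deg_sets = {}
        for term in config.go_filter_terms:
            if term not in graph:
                continue
            members = go_filter_transcripts(annotation, graph, term)
            deg_sets[term] = sorted(set(members) & set(degs))
            if len(members) < 2:
                continue
            emb = phen_mod.phenotype_pipeline(
                log2, gene_subset=sorted(members), samples=samples,
                perplexity=config.perplexity, iterations=config.iterations,
                repeats=config.repeats, min_pts=config.min_pts, seed=config.seed,
            )
            filter_summaries[term] = _write_embedding(
                emb, outdir, term.replace(":", "_"))
            filter_summaries[term]["filter_size"] = len(members)
        manifest["stages"]["go_filters"] = filter_summaries

        panels = {}
        for direction in ("field_up", "culture_up"):
            p = panel_mod.build_panel(z, deg_sets, samples, direction)
            panel_mod.write_panel(p, outdir / f"panel_{direction}.tsv")
            panels[direction] = len(p)
            if len(p.transcripts) >= 2:
                render_heatmap(z, sorted(p.transcripts), samples,
                               outdir / f"heatmap_panel_{direction}.tsv",
                               outdir / f"heatmap_panel_{direction}.png")
        manifest["stages"]["panels"] = panels

    # contamination check
    if config.markers_path and Path(config.markers_path).exists():
        markers = pd.read_csv(config.markers_path, sep="\t", index_col=0)
        comp = species_mod.estimate_composition(markers)
        frame = comp.proportions.copy()
        frame["expected_cross_mapped_fraction"] = species_mod.expected_cross_mapping(comp)
        frame.to_csv(outdir / "species_composition.tsv", sep="\t",
                     index_label="sample_id")
        flagged = catalog.index[catalog["cross_map_flag"]]
        if len(flagged):
            cmp_result = species_mod.exclusion_comparison(
                log2, flagged, samples=samples, seed=config.seed,
                perplexity=config.perplexity, iterations=config.iterations,
                repeats=config.repeats, min_pts=config.min_pts,
            )
            manifest["stages"]["contamination"] = {
                "ari": cmp_result["ari"],
                "n_clusters_with": cmp_result["n_clusters_with"],
                "n_clusters_without": cmp_result["n_clusters_without"],
                "n_excluded": cmp_result["n_excluded"],
            }
    elif config.markers_path:
        log.warning("marker file %s missing; contamination stage skipped",
                    config.markers_path)
        manifest["stages"]["contamination"] = "skipped: marker file missing"

    cfg = {k: v for k, v in vars(config).items() if k != "extra"}
    cfg["go_filter_terms"] = list(config.go_filter_terms)
    manifest["config"] = cfg
    manifest["parameter_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
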