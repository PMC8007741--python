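"""Designer indicator panels: strict z-score non-overlap selection.

From the DEGs annotated to the three filter terms, keep transcripts whose
z-scores show no overlap between field (diapause program) and culture
(reproductive program) samples, in each direction.  Writes both panels
with per-term provenance, clustered z-score heatmaps, and the
panel-restricted embedding, which separates the two programs.
"""

from pathlib import Path

from diapausetx import expression as ex
from diapausetx import panel as pn
from diapausetx import phenotype as ph
from diapausetx import simulate as sim
from diapausetx.report import render_heatmap
from diapausetx.ontology import go_filter_transcripts, parse_obo

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts, catalog, samples = ex.read_counts(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "catalog.tsv",
        ROOT / "data" / "samples.tsv")
    graph = parse_obo(ROOT / "data" / "ontology.obo")
    annotation = {t: catalog.loc[t, "go_terms"] for t in catalog.index
                  if catalog.loc[t, "go_terms"]}
    degs = set((ROOT / "de" / "deg_ids.txt").read_text().split())
    ladder = ex.normalization_ladder(counts, catalog)
    deg_sets = {}
    for tag in ("oogenesis_like", "fatty_acid_like", "rna_metabolism_like"):
        term = sim.tag_term(tag)
        members = go_filter_transcripts(annotation, graph, term)
        deg_sets[term] = sorted(set(members) & degs)

    out = ROOT / "panels"
    out.mkdir(parents=True, exist_ok=True)
    union = set()
    for direction in ("field_up", "culture_up"):
        panel = pn.build_panel(ladder["zscore"], deg_sets, samples, direction)
        pn.write_panel(panel, out / f"panel_{direction}.tsv")
        union |= panel.transcripts
        per_term = {t: len(ids) for t, ids in panel.per_term.items()}
        print(f"{direction}: {len(panel)} transcripts {per_term}")
        if len(panel.transcripts) >= 2:
            render_heatmap(ladder["zscore"], sorted(panel.transcripts),
                           samples, out / f"heatmap_{direction}.tsv",
                           out / f"heatmap_{direction}.png")

    res = ph.phenotype_pipeline(ladder["log2rpkm"], gene_subset=sorted(union),
                                samples=samples, seed=0, repeats=10)
    coords = res.coordinates.copy()
    coords["cluster"] = res.labels
    coords.to_csv(out / "embedding_panel.tsv", sep="\t",
                  index_label="sample_id")
    print(f"panel-restricted embedding: {res.n_clusters} clusters")
    print(res.contingency)


if __name__ == "__main__":
    main()
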