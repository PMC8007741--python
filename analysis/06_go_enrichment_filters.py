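"""Strategies 2b/3: GO enrichment of the DEGs and GO-filtered embeddings.

Fisher enrichment (classic per-term test, BH-corrected) of the DEG set
against all GO-annotated transcripts, then t-SNE + DBSCAN/Dunn on the
transcripts under each filter term (oogenesis-like, fatty-acid-like,
RNA-metabolism-like and their closures).  On the synthetic study data
only the RNA-metabolism-like filter splits the samples cleanly by
developmental program; the oogenesis-like filter isolates late culture.
"""

from pathlib import Path

from diapausetx import expression as ex
from diapausetx import phenotype as ph
from diapausetx import simulate as sim
from diapausetx.ontology import (fisher_enrichment, go_filter_transcripts,
                                 parse_obo, write_enrichment)

ROOT = Path(__file__).resolve().parents[1] / "results"
FILTER_TAGS = ("oogenesis_like", "fatty_acid_like", "rna_metabolism_like")


def main() -> None:
    counts, catalog, samples = ex.read_counts(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "catalog.tsv",
        ROOT / "data" / "samples.tsv")
    graph = parse_obo(ROOT / "data" / "ontology.obo")
    annotation = {t: catalog.loc[t, "go_terms"] for t in catalog.index
                  if catalog.loc[t, "go_terms"]}
    degs = set((ROOT / "de" / "deg_ids.txt").read_text().split())
    out = ROOT / "go"
    out.mkdir(parents=True, exist_ok=True)

    universe = sorted(annotation)
    study = sorted(degs & set(universe))
    table = fisher_enrichment(study, universe, annotation, graph)
    write_enrichment(table, out / "enrichment_degs.tsv")
    enriched = table[table["enriched"]]
    print(f"{len(enriched)} of {len(table)} terms enriched among "
          f"{len(study)} annotated DEGs:")
    print(enriched[["name", "study_count", "universe_count", "fdr"]]
          .round(4).to_string())

    log2 = ex.log_transform(ex.compute_rpkm(counts, catalog))
    for tag in FILTER_TAGS:
        term = sim.tag_term(tag)
        members = go_filter_transcripts(annotation, graph, term)
        res = ph.phenotype_pipeline(log2, gene_subset=sorted(members),
                                    samples=samples, seed=0, repeats=10)
        coords = res.coordinates.copy()
        coords["cluster"] = res.labels
        coords.to_csv(out / f"embedding_{tag}.tsv", sep="\t",
                      index_label="sample_id")
        print(f"\n{tag} filter ({len(members)} transcripts): "
              f"{res.n_clusters} clusters, stability {res.stability:.2f}")
        print(res.contingency)


if __name__ == "__main__":
    main()
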