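"""Generate the synthetic study dataset with planted truth.

Emulates the study design: 16 samples (EF/LF field = diapause program,
EC/LC culture = reproductive program, 4 replicates each), NB counts with
program effects concentrated in GO-tagged gene sets, planted co-expression
modules, strict-separation indicator genes and congener contamination.
Writes counts/catalog/samples TSV, the toy ontology and truth JSON under
results/data/.
"""

from pathlib import Path

from diapausetx import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    config = sim.SimulationConfig()
    counts, catalog, samples, truth = sim.generate_dataset(config)
    graph, annotation = sim.generate_ontology(config, truth)
    sim.write_dataset(OUT, counts, catalog, samples, truth, graph, annotation)
    print(f"wrote {counts.shape[0]} transcripts x {counts.shape[1]} samples "
          f"to {OUT}")
    print(f"planted: {len(truth.indicator_ids['field_up'])} field-up and "
          f"{len(truth.indicator_ids['culture_up'])} culture-up indicators, "
          f"{(truth.module_labels != '0').sum()} module genes, "
          f"{len(truth.contaminated_ids)} cross-map-prone transcripts")


if __name__ == "__main__":
    main()
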