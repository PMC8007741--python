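"""Strategy 2: NB-GLM differential expression.

cpm filter (>=1 cpm in >=4 of 16 samples), TMM normalization, tagwise
dispersions, the global 4-group likelihood-ratio test and all six
pairwise contrasts at BH-FDR 0.05.  Prints the per-contrast DEG table
(total / up / down, the Table-1-style summary) and writes one TSV per
contrast under results/de/.
"""

from pathlib import Path

from diapausetx import de as de_mod
from diapausetx import expression as ex

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts, catalog, samples = ex.read_counts(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "catalog.tsv",
        ROOT / "data" / "samples.tsv")
    results, degs = de_mod.run_de(counts, samples, alpha=0.05)
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    print(f"{'contrast':10s} {'DEGs':>6s} {'up':>6s} {'down':>6s}")
    for label, res in results.items():
        de_mod.write_de_table(res, out / f"de_{label}.tsv")
        sig = res.table[res.table["fdr"] <= 0.05]
        up = int((sig["direction"] == "up").sum())
        down = int((sig["direction"] == "down").sum())
        print(f"{label:10s} {len(sig):6d} {up:6d} {down:6d}")
    (out / "deg_ids.txt").write_text("\n".join(sorted(degs)) + "\n")
    print(f"downstream DEG set (global test): {len(degs)} transcripts")


if __name__ == "__main__":
    main()
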