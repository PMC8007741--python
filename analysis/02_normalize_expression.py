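"""Compute the normalization ladder: RPKM -> log2(RPKM+1) -> z-scores.

Writes all three stages as TSV under results/expression/ (the same trio
the study deposited alongside raw counts).
"""

from pathlib import Path

from diapausetx import expression as ex

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts, catalog, _ = ex.read_counts(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "catalog.tsv",
        ROOT / "data" / "samples.tsv")
    out = ROOT / "expression"
    out.mkdir(parents=True, exist_ok=True)
    ladder = ex.normalization_ladder(counts, catalog)
    for stage, mat in ladder.items():
        ex.write_expression(mat, out / f"expression_{stage}.tsv")
    n_flat = len(ladder["zscore"].zero_variance)
    print(f"wrote rpkm / log2rpkm / zscore for {counts.shape[0]} transcripts; "
          f"{n_flat} zero-variance rows flagged")


if __name__ == "__main__":
    main()
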