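"""Count-matrix IO and the normalization ladder: RPKM -> log2(RPKM+1) -> z-scores.

Relative expression of transcript ``i`` in sample ``j`` is

    RPKM(i, j) = reads(i, j) / [(length(i) / 1000) * (mapped_reads(j) / 1e6)]

with ``mapped_reads(j)`` taken as the column sum of the count matrix.
Log-transformed values use a pseudocount of 1, log2(RPKM + 1); z-scores
standardize each transcript across samples (sample SD, n-1) and feed the
heatmaps and the indicator ("designer") filters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_ORDER = ("EF", "LF", "EC", "LC")

_SOURCE_TIME_TO_GROUP = {
    ("field", "early"): "EF",
    ("field", "late"): "LF",
    ("culture", "early"): "EC",
    ("culture", "late"): "LC",
}


@dataclass
class ExpressionMatrix:
    """Real-valued transform of counts with a named normalization stage.

    stage is one of ``rpkm``, ``log2rpkm`` or ``zscore``.  ``zero_variance``
    lists transcripts whose z-score row was set to all-zero because the
    transcript did not vary across samples.
    """

    values: pd.DataFrame
    stage: str
    zero_variance: tuple[str, ...] = field(default_factory=tuple)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids if t in self.values.index]
        return ExpressionMatrix(
            self.values.loc[ids],
            self.stage,
            tuple(t for t in self.zero_variance if t in set(ids)),
        )


def derive_group(source: str, timepoint: str) -> str:
    try:
        return _SOURCE_TIME_TO_GROUP[(source, timepoint)]
    except KeyError:
        raise ValueError(f"unknown source/timepoint combination: {source!r}/{timepoint!r}")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Enforce the CountMatrix contract: unique ids, integer counts >= 0."""
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if counts.shape[1] < 1:
        raise ValueError("count matrix needs at least one sample")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        counts = counts.round().astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def read_counts(
    path: str | Path,
    catalog_path: str | Path,
    samples_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the counts/catalog/sample-table TSV triple and cross-validate.

    Returns ``(counts, catalog, samples)`` where counts is transcripts x
    samples (int64), catalog is indexed by transcript id with ``length_bp``,
    ``annotation``, ``go_terms`` (frozenset) and ``cross_map_flag`` columns,
    and samples is indexed by sample id with ``source``, ``timepoint``,
    ``group`` and ``replicate`` columns.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts = validate_counts(counts)
    catalog = read_catalog(catalog_path)
    samples = read_samples(samples_path)

    missing = counts.index.difference(catalog.index)
    if len(missing):
        raise ValueError(f"transcripts absent from catalog: {list(missing[:5])}")
    missing_samples = counts.columns.difference(samples.index)
    if len(missing_samples):
        raise ValueError(f"samples absent from sample table: {list(missing_samples)}")
    return counts, catalog, samples


def read_catalog(path: str | Path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", index_col=0, dtype={"annotation": "string"})
    if catalog.index.duplicated().any():
        raise ValueError("duplicate transcript ids in catalog")
    if (catalog["length_bp"] < 1).any():
        raise ValueError("transcript lengths must be >= 1 bp")
    go = catalog.get("go_terms")
    if go is None:
        catalog["go_terms"] = [frozenset()] * len(catalog)
    else:
        catalog["go_terms"] = [
            frozenset(str(v).split(";")) if isinstance(v, str) and v else frozenset()
            for v in go.fillna("")
        ]
    if "cross_map_flag" not in catalog:
        catalog["cross_map_flag"] = False
    catalog["cross_map_flag"] = catalog["cross_map_flag"].astype(bool)
    return catalog


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample ids")
    samples["group"] = [
        derive_group(s, t) for s, t in zip(samples["source"], samples["timepoint"])
    ]
    return samples


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    out["go_terms"] = [";".join(sorted(s)) for s in out["go_terms"]]
    out.to_csv(path, sep="\t", index_label="transcript_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="transcript_id")


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def compute_rpkm(counts: pd.DataFrame, catalog: pd.DataFrame) -> ExpressionMatrix:
    """Reads per kilobase of transcript length per million mapped reads."""
    counts = validate_counts(counts)
    missing = counts.index.difference(catalog.index)
    if len(missing):
        raise ValueError(f"no length for transcripts: {list(missing[:5])}")
    libs = library_sizes(counts)
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    len_kb = catalog.loc[counts.index, "length_bp"].to_numpy(dtype=float) / 1000.0
    per_million = libs.to_numpy(dtype=float) / 1e6
    values = counts.to_numpy(dtype=float) / (len_kb[:, None] * per_million[None, :])
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.index, columns=counts.columns), "rpkm"
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(RPKM + 1); monotone, maps 0 to 0."""
    if expr.stage != "rpkm":
        raise ValueError(f"log_transform expects stage 'rpkm', got {expr.stage!r}")
    if (expr.values.to_numpy() < 0).any():
        raise ValueError("negative values in RPKM matrix")
    return ExpressionMatrix(np.log2(expr.values + 1.0), "log2rpkm")


def zscore(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each transcript across samples (mean 0, sample SD 1).

    Zero-variance rows become all-zero and are recorded in
    ``zero_variance`` — such transcripts carry no relative-expression
    signal and can never pass the strict non-overlap filter.
    """
    if expr.stage != "log2rpkm":
        raise ValueError(f"zscore expects stage 'log2rpkm', got {expr.stage!r}")
    if expr.values.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns),
        "zscore",
        tuple(expr.values.index[flat]),
    )


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libs = library_sizes(counts)
    if (libs == 0).any():
        raise ValueError("zero library size")
    return counts / libs.to_numpy(dtype=float) * 1e6


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 4
) -> pd.DataFrame:
    """Drop transcripts lacking >= min_cpm in at least min_samples samples.

    cpm is computed on raw library sizes (before TMM), matching the
    conventional filter-then-normalize order.
    """
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def normalization_ladder(
    counts: pd.DataFrame, catalog: pd.DataFrame
) -> dict[str, ExpressionMatrix]:
    """All three stages at once: rpkm, log2rpkm, zscore."""
    rpkm = compute_rpkm(counts, catalog)
    log2 = log_transform(rpkm)
    return {"rpkm": rpkm, "log2rpkm": log2, "zscore": zscore(log2)}
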