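"""Congener-contamination workflow: species composition from mtCOI marker
reads, expected cross-mapping levels, and a paired embedding comparison
excluding cross-map-prone transcripts.

Field samples can contain morphologically indistinguishable congeners
whose reads partially cross-map onto the focal reference.  Composition is
estimated from reads on species-diagnostic mtCOI marker transcripts; the
expected cross-mapped read fraction is (non-focal share) x (cross-mapping
efficiency, default 0.30).  The robustness check repeats the phenotype
protocol with and without the flagged transcripts and reports the
adjusted Rand index between the two partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .expression import ExpressionMatrix
from .phenotype import phenotype_pipeline

DEFAULT_CROSS_MAP_EFFICIENCY = 0.30


@dataclass
class CompositionEstimate:
    proportions: pd.DataFrame  # samples x species
    focal_species: str

    def congener_share(self) -> pd.Series:
        return 1.0 - self.proportions[self.focal_species]


def estimate_composition(markers: pd.DataFrame, focal_species: str | None = None
                         ) -> CompositionEstimate:
    """Per-sample species proportions from marker-transcript read counts.

    ``markers`` is samples x species.  The focal species defaults to the
    first column.
    """
    if markers.shape[1] < 1:
        raise ValueError("need at least one species")
    if (markers.to_numpy() < 0).any():
        raise ValueError("marker counts must be non-negative")
    totals = markers.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero marker total for samples: {list(zero.index)}")
    props = markers.div(totals, axis=0)
    return CompositionEstimate(props, focal_species or markers.columns[0])


def expected_cross_mapping(
    composition: CompositionEstimate,
    efficiency: float = DEFAULT_CROSS_MAP_EFFICIENCY,
) -> pd.Series:
    """Expected fraction of each library attributable to cross-mapped
    congener reads: (sum of non-focal proportions) x efficiency."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    frac = composition.congener_share() * efficiency
    frac.name = "expected_cross_mapped_fraction"
    return frac


def flag_cross_map_prone(
    congener_counts: pd.DataFrame, min_cpm: float = 1.0
) -> frozenset:
    """Transcripts receiving >= min_cpm from the congener read set in any
    sample (the qualitative 'most cross-map-prone' criterion made
    operational)."""
    libs = congener_counts.sum(axis=0)
    libs = libs.where(libs > 0, other=1.0)
    cpm = congener_counts / libs * 1e6
    return frozenset(congener_counts.index[(cpm >= min_cpm).any(axis=1)])


def exclusion_comparison(
    expr: ExpressionMatrix,
    flagged_ids: Sequence[str],
    samples: pd.DataFrame | None = None,
    gene_subset: Sequence[str] | None = None,
    seed: int = 0,
    **pipeline_kwargs,
) -> dict:
    """Paired phenotype embeddings with and without flagged transcripts.

    Both runs use the same seed policy; reports the adjusted Rand index
    between the two DBSCAN partitions and each run's cluster count.
    """
    universe = list(gene_subset) if gene_subset is not None else list(expr.values.index)
    flagged = set(flagged_ids)
    kept = [t for t in universe if t not in flagged]
    if not kept:
        raise ValueError("excluding flagged transcripts empties the gene set")
    with_result = phenotype_pipeline(
        expr, gene_subset=universe, samples=samples, seed=seed, **pipeline_kwargs
    )
    without_result = phenotype_pipeline(
        expr, gene_subset=kept, samples=samples, seed=seed, **pipeline_kwargs
    )
    ari = float(
        adjusted_rand_score(with_result.labels.to_numpy(),
                            without_result.labels.to_numpy())
    )
    if np.array_equal(with_result.labels.to_numpy(), without_result.labels.to_numpy()):
        ari = 1.0
    return {
        "ari": ari,
        "with": with_result,
        "without": without_result,
        "n_clusters_with": with_result.n_clusters,
        "n_clusters_without": without_result.n_clusters,
        "n_excluded": len(universe) - len(kept),
    }
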