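"""Transcriptional-phenotype protocol: t-SNE over samples, DBSCAN with
MinPts = 3, and objective Eps selection by Dunn-index maximization.

Samples (not genes) are the embedded points; features are log2(RPKM+1)
values of all genes or of a GO-filtered subset.  t-SNE (perplexity 5, up
to 50,000 iterations) is run repeatedly; the representative run is the one
with the lowest final KL divergence and the fraction of repeats whose
DBSCAN partition matches it is reported as a stability score.  The DBSCAN
Eps cut-off is scanned over every unique pairwise distance in the
embedding and chosen to maximize the Dunn index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .expression import ExpressionMatrix
from .ontology import OntologyGraph, go_filter_transcripts


@dataclass
class EmbeddingResult:
    """Representative 2-D embedding with its DBSCAN partition and diagnostics."""

    coordinates: pd.DataFrame  # samples x (tsne1, tsne2)
    labels: pd.Series  # -1 = noise
    eps: float
    dunn: float | None
    perplexity: float
    iterations: int
    seed: int
    kl_per_repeat: tuple[float, ...]
    stability: float
    repeat_labels: tuple[tuple[int, ...], ...] = field(default=(), repr=False)
    contingency: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels) - {-1}))

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())


def embed_tsne(
    expr: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    perplexity: float = 5.0,
    iterations: int = 50_000,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    """Repeated t-SNE of samples; returns (representative coords,
    all repeat coords, final KL divergence per repeat).

    The representative run is the repeat with the lowest KL divergence.
    Requires n_samples >= 3 * perplexity + 1 so each point has a full
    perplexity neighborhood.
    """
    if gene_subset is not None:
        ids = [g for g in gene_subset if g in expr.values.index]
        if len(ids) == 0:
            raise ValueError("empty gene subset")
        features = expr.values.loc[ids]
    else:
        features = expr.values
    x = features.to_numpy(dtype=float).T  # samples x genes
    n = x.shape[0]
    if n < 3 * perplexity + 1:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples "
            f"(need n >= 3*perplexity + 1)"
        )
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    coords, kls = [], []
    for s in run_seeds:
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            max_iter=iterations,
            init="random",
            random_state=int(s),
            method="exact",
        )
        coords.append(tsne.fit_transform(x))
        kls.append(float(tsne.kl_divergence_))
    best = int(np.argmin(kls))
    return coords[best], coords, kls


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Classic Dunn index: minimum single-linkage inter-cluster distance
    over maximum complete-linkage intra-cluster diameter.

    Noise points (label -1) are excluded.  A zero overall diameter (all
    clusters internally duplicated points) returns +inf.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    keep = labels != -1
    points, labels = points[keep], labels[keep]
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    dist = squareform(pdist(points))
    min_between = np.inf
    max_within = 0.0
    for i, a in enumerate(clusters):
        ia = labels == a
        sub = dist[np.ix_(ia, ia)]
        if ia.sum() > 1:
            max_within = max(max_within, float(sub.max()))
        for b in clusters[i + 1:]:
            ib = labels == b
            min_between = min(min_between, float(dist[np.ix_(ia, ib)].min()))
    if max_within == 0.0:
        return float("inf")
    return min_between / max_within


def dbscan_labels(points: np.ndarray, eps: float, min_pts: int = 3) -> np.ndarray:
    """Deterministic DBSCAN.

    A point's Eps-neighborhood includes itself; core points have >= min_pts
    neighbors; clusters are connected components of core points at
    distance <= Eps; border points join the cluster of their lowest-index
    core neighbor; everything else is noise (-1).  Cluster ids are numbered
    by each cluster's smallest member index, so labels never depend on
    point order.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    dist = squareform(pdist(points))
    neighbors = dist <= eps
    core = neighbors.sum(axis=1) >= min_pts

    labels = np.full(n, -1, dtype=int)
    cluster_id = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cluster_id
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(neighbors[j] & core):
                    if labels[k] == -1:
                        labels[k] = cluster_id
                        stack.append(int(k))
            cluster_id += 1
    for i in range(n):
        if labels[i] == -1 and not core[i]:
            core_neighbors = np.flatnonzero(neighbors[i] & core)
            if core_neighbors.size:
                labels[i] = labels[core_neighbors[0]]
    # renumber clusters by smallest member index
    order = {}
    for i in range(n):
        if labels[i] != -1 and labels[i] not in order:
            order[labels[i]] = len(order)
    return np.array([order[l] if l != -1 else -1 for l in labels])


def cluster_embedding(
    points: np.ndarray, min_pts: int = 3
) -> tuple[np.ndarray, float, float | None]:
    """DBSCAN with Eps chosen to maximize the Dunn index.

    Candidate Eps values are all unique pairwise distances.  Only
    configurations with >= 2 clusters compete; ties go to the smallest
    Eps.  When scoring a candidate partition, DBSCAN's noise points are
    treated as one additional group (a diffuse noise set has a large
    diameter, so partitions that shed most points as noise score poorly
    — evaluating the full partition the way the protocol's Dunn
    implementation does).  The returned Dunn value for the chosen
    partition is the classic noise-excluded index.  If no Eps yields
    >= 2 clusters the fallback is one cluster at Eps = max distance with
    Dunn undefined (None).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < min_pts:
        raise ValueError("fewer points than MinPts")
    dists = np.unique(pdist(points))
    dists = dists[dists > 0]
    best = None
    for eps in dists:
        labels = dbscan_labels(points, eps, min_pts)
        if len(set(labels.tolist()) - {-1}) < 2:
            continue
        score = dunn_index(points, _noise_as_cluster(labels))
        key = (score, -int((labels == -1).sum()))
        if best is None or key > best[0]:
            best = (key, float(eps), labels)
    if best is None:
        eps = float(dists.max()) if dists.size else 0.0
        return np.zeros(points.shape[0], dtype=int), eps, None
    _, eps, labels = best
    return labels, eps, dunn_index(points, labels)


def _noise_as_cluster(labels: np.ndarray) -> np.ndarray:
    """Relabel noise (-1) as one extra group for partition scoring."""
    if (labels == -1).any():
        out = labels.copy()
        out[out == -1] = labels.max() + 1
        return out
    return labels


def _partition_key(labels: np.ndarray) -> tuple:
    """Canonical form of a partition, invariant to label names."""
    seen: dict[int, int] = {}
    out = []
    for l in labels:
        if l == -1:
            out.append(-1)
        else:
            out.append(seen.setdefault(l, len(seen)))
    return tuple(out)


def phenotype_pipeline(
    expr: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    go_term: str | None = None,
    graph: OntologyGraph | None = None,
    annotation=None,
    samples: pd.DataFrame | None = None,
    perplexity: float = 5.0,
    iterations: int = 50_000,
    repeats: int = 10,
    min_pts: int = 3,
    seed: int = 0,
) -> EmbeddingResult:
    """GO filter (optional) -> repeated t-SNE -> DBSCAN/Dunn clustering.

    The DBSCAN/Dunn protocol is applied to every repeat; the reported
    partition comes from the minimum-KL representative run and stability
    is the fraction of repeats whose partition matches it.
    """
    if go_term is not None:
        if graph is None or annotation is None:
            raise ValueError("go_term requires graph and annotation")
        gene_subset = sorted(go_filter_transcripts(annotation, graph, go_term))
        if len(gene_subset) < 2:
            raise ValueError(f"GO filter {go_term} resolves to <2 genes")
    rep_coords, all_coords, kls = embed_tsne(
        expr, gene_subset, perplexity, iterations, repeats, seed
    )
    per_repeat = [cluster_embedding(c, min_pts) for c in all_coords]
    best = int(np.argmin(kls))
    labels, eps, dunn = per_repeat[best]
    rep_key = _partition_key(labels)
    stability = float(
        np.mean([_partition_key(l) == rep_key for l, _, _ in per_repeat])
    )
    sample_ids = expr.values.columns
    labels_s = pd.Series(labels, index=sample_ids, name="cluster")
    contingency = None
    if samples is not None:
        contingency = pd.crosstab(labels_s, samples.loc[sample_ids, "group"])
    return EmbeddingResult(
        coordinates=pd.DataFrame(rep_coords, index=sample_ids, columns=["tsne1", "tsne2"]),
        labels=labels_s,
        eps=eps,
        dunn=dunn,
        perplexity=perplexity,
        iterations=iterations,
        seed=seed,
        kl_per_repeat=tuple(kls),
        stability=stability,
        repeat_labels=tuple(tuple(int(v) for v in l) for l, _, _ in per_repeat),
        contingency=contingency,
    )
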