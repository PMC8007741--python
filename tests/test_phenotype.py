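"""t-SNE embedding, Dunn index, deterministic DBSCAN and Eps selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from diapausetx import phenotype as ph
from diapausetx.expression import ExpressionMatrix


def _expr(n_genes=30, n_samples=16, seed=40):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(3, 1, size=(n_genes, n_samples)),
                     index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n_samples)]),
        "log2rpkm",
    )


def test_embed_shape_and_kl_diagnostics():
    coords, all_coords, kls = ph.embed_tsne(_expr(), repeats=3, iterations=1000,
                                            seed=0)
    assert coords.shape == (16, 2)
    assert len(all_coords) == 3 and len(kls) == 3
    assert np.isfinite(coords).all()
    assert kls[int(np.argmin(kls))] == min(kls)


def test_embed_perplexity_guard_and_empty_subset():
    with pytest.raises(ValueError, match="perplexity"):
        ph.embed_tsne(_expr(n_samples=8), perplexity=5, repeats=1)
    with pytest.raises(ValueError, match="empty"):
        ph.embed_tsne(_expr(), gene_subset=["nope"], repeats=1)


def test_embed_places_duplicate_samples_together():
    rng = np.random.default_rng(41)
    vals = rng.normal(size=(40, 16))
    vals[:, 1] = vals[:, 0]  # duplicate sample profiles
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(40)],
                     columns=[f"s{j}" for j in range(16)]), "log2rpkm")
    _, all_coords, _ = ph.embed_tsne(expr, repeats=10, iterations=2000, seed=1)
    hits = 0
    for coords in all_coords:
        d_dup = np.linalg.norm(coords[0] - coords[1])
        med = np.median(pdist(coords))
        hits += d_dup < med
    assert hits >= 9


def dunn_oracle(points, labels):
    """Brute force over all pairwise distances."""
    points = np.asarray(points, dtype=float)
    keep = labels != -1
    points, labels = points[keep], labels[keep]
    clusters = sorted(set(labels))
    inter = min(
        np.linalg.norm(points[i] - points[j])
        for i, j in itertools.combinations(range(len(points)), 2)
        if labels[i] != labels[j]
    )
    intra = max(
        (np.linalg.norm(points[i] - points[j])
         for i, j in itertools.combinations(range(len(points)), 2)
         if labels[i] == labels[j]),
        default=0.0,
    )
    return inter / intra if intra > 0 else float("inf")


def test_dunn_two_interval_example():
    pts = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
    labels = np.array([0, 0, 1, 1])
    assert ph.dunn_index(pts, labels) == pytest.approx(9.0)
    assert dunn_oracle(pts, labels) == pytest.approx(9.0)


def test_dunn_scale_invariance_and_errors():
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(12, 2))
    labels = np.array([0] * 6 + [1] * 6)
    d = ph.dunn_index(pts, labels)
    assert ph.dunn_index(pts * 7.3, labels) == pytest.approx(d)
    with pytest.raises(ValueError):
        ph.dunn_index(pts, np.zeros(12, dtype=int))
    dup = np.vstack([pts[:2], pts[:2]])
    assert ph.dunn_index(dup, np.array([0, 1, 0, 1])) == float("inf")


def test_dunn_matches_oracle_random_partitions():
    rng = np.random.default_rng(43)
    for _ in range(100):
        n = int(rng.integers(6, 16))
        pts = rng.normal(size=(n, 2))
        labels = rng.integers(0, 3, size=n)
        labels[rng.random(n) < 0.2] = -1
        if len(set(labels.tolist()) - {-1}) < 2:
            continue
        assert ph.dunn_index(pts, labels) == pytest.approx(
            dunn_oracle(pts, labels))


def dbscan_oracle(points, eps, min_pts):
    """Literal definition: core points, core connectivity, border points to
    the lowest-index core neighbor."""
    n = len(points)
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for i in np.flatnonzero(core):
        if labels[i] != -1:
            continue
        comp = {i}
        frontier = {i}
        while frontier:
            nxt = set()
            for j in frontier:
                for k in np.flatnonzero(neigh[j] & core):
                    if k not in comp:
                        comp.add(int(k))
                        nxt.add(int(k))
            frontier = nxt
        for j in comp:
            labels[j] = cid
        cid += 1
    for i in range(n):
        if labels[i] == -1 and not core[i]:
            cores = [j for j in np.flatnonzero(neigh[i]) if core[j]]
            if cores:
                labels[i] = labels[cores[0]]
    remap = {}
    out = []
    for l in labels:
        if l == -1:
            out.append(-1)
        else:
            out.append(remap.setdefault(l, len(remap)))
    return np.array(out)


def test_dbscan_matches_oracle_and_order_invariance():
    rng = np.random.default_rng(44)
    for _ in range(60):
        pts = rng.normal(size=(int(rng.integers(6, 18)), 2))
        eps = float(rng.uniform(0.3, 2.0))
        mine = ph.dbscan_labels(pts, eps, 3)
        np.testing.assert_array_equal(mine, dbscan_oracle(pts, eps, 3))
    pts = rng.normal(size=(14, 2))
    eps = 1.0
    base = ph.dbscan_labels(pts, eps, 3)
    perm = rng.permutation(14)
    permuted = ph.dbscan_labels(pts[perm], eps, 3)
    # same partition after undoing the permutation
    back = np.empty(14, dtype=int)
    back[perm] = permuted
    joint = {}
    for a, b in zip(base, back):
        joint.setdefault(a, set()).add(b)
    assert all(len(v) == 1 for v in joint.values())


def eps_scan_oracle(points, min_pts=3):
    """Exhaustive scan over unique pairwise distances with the same
    scoring rule, written independently."""
    dists = sorted(set(pdist(points)))
    best = None
    for eps in dists:
        if eps <= 0:
            continue
        labels = dbscan_oracle(points, eps, min_pts)
        k = len(set(labels.tolist()) - {-1})
        if k < 2:
            continue
        scored = labels.copy()
        scored[scored == -1] = scored.max() + 1
        score = dunn_oracle(points, scored)
        key = (score, -int((labels == -1).sum()))
        if best is None or key > best[0]:
            best = (key, eps, labels)
    return best


def test_two_blob_eps_selection_matches_oracle():
    rng = np.random.default_rng(45)
    blob_a = rng.normal(0, 0.4, size=(8, 2))
    blob_b = rng.normal(8, 0.4, size=(8, 2))
    pts = np.vstack([blob_a, blob_b])
    labels, eps, dunn = ph.cluster_embedding(pts)
    assert len(set(labels.tolist())) == 2 and (labels != -1).all()
    _, eps_oracle, labels_oracle = eps_scan_oracle(pts)
    assert eps == pytest.approx(eps_oracle)
    np.testing.assert_array_equal(labels, labels_oracle)
    assert dunn == pytest.approx(ph.dunn_index(pts, labels))


def test_eps_selection_matches_oracle_random_instances():
    rng = np.random.default_rng(46)
    for _ in range(25):
        centers = rng.normal(0, 6, size=(int(rng.integers(2, 4)), 2))
        pts = np.vstack([
            c + rng.normal(0, 0.7, size=(int(rng.integers(3, 7)), 2))
            for c in centers
        ])
        if len(pts) > 20:
            continue
        labels, eps, _ = ph.cluster_embedding(pts)
        oracle = eps_scan_oracle(pts)
        if oracle is None:
            assert len(set(labels.tolist())) == 1
            continue
        assert eps == pytest.approx(oracle[1])
        np.testing.assert_array_equal(labels, oracle[2])


def test_equidistant_points_fall_back_to_single_cluster():
    # regular simplex corners in high dimension projected: use 3 points
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    labels, eps, dunn = ph.cluster_embedding(pts, min_pts=3)
    assert set(labels.tolist()) == {0}
    assert dunn is None
    with pytest.raises(ValueError):
        ph.cluster_embedding(pts[:2], min_pts=3)


def test_pipeline_requires_ontology_inputs():
    with pytest.raises(ValueError, match="graph"):
        ph.phenotype_pipeline(_expr(), go_term="GO:0000001")
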