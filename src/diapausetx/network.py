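"""Weighted co-expression modules on the DEG expression matrix.

Unsigned adjacency a_ij = |cor(i,j)|^beta (soft threshold, default beta=14)
is smoothed into the topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

modules are cut from average-linkage clustering of 1 - TOM, small clusters
fall into the unassigned "grey" bin, and modules with nearly identical
eigengenes are merged.  The module eigengene is the first principal
component of the module's standardized expression; module-trait
relationships are Pearson correlations of eigengenes against group and
sample indicator variables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist

from . import expression as expr_mod

# WGCNA's standard color sequence, assigned by decreasing module size;
# grey is reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
UNASSIGNED = "grey"


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd[~ok] = 1.0
    return (values - mean) / sd, ok


def tom_similarity(expr, beta: int = 14) -> pd.DataFrame:
    """Topological overlap matrix from an expression matrix (genes x samples).

    Accepts an ExpressionMatrix or a DataFrame.  Zero-variance rows are
    dropped with a warning.  Diagonal is 1; values lie in [0, 1].
    """
    values = expr.values if hasattr(expr, "stage") else expr
    if values.shape[1] < 3:
        raise ValueError("TOM needs at least 3 samples")
    z, ok = _standardize_rows(values.to_numpy(dtype=float))
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance transcripts")
    ids = values.index[ok]
    z = z[ok]
    n = z.shape[1]
    corr = np.clip(z @ z.T / (n - 1), -1.0, 1.0)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    min_k = np.minimum.outer(k, k)
    tom = (shared + adj) / (min_k + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=ids, columns=ids)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 100,
    cut_height: float = 0.99,
    merge_threshold: float = 0.25,
    expr=None,
) -> pd.Series:
    """Assign module color labels from a TOM.

    Average-linkage clustering of 1 - TOM, static cut at ``cut_height``;
    clusters below ``min_size`` become grey; modules whose eigengenes
    correlate above 1 - merge_threshold are merged (needs ``expr`` to
    compute eigengenes; skipped otherwise with a warning when more than
    one module exists).  Colors are assigned by decreasing size, largest
    module = turquoise.
    """
    if tom.shape[0] == 0:
        raise ValueError("empty TOM")
    if tom.shape[0] == 1:
        return pd.Series([UNASSIGNED], index=tom.index, name="module")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size].index
    labels = labels.where(labels.isin(keep), other=-1)

    if expr is not None and len(keep) > 1:
        labels = _merge_close_modules(labels, expr, merge_threshold)

    sizes = labels[labels != -1].value_counts()
    color_of = {c: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
                for i, c in enumerate(sizes.index)}
    out = labels.map(lambda c: UNASSIGNED if c == -1 else color_of[c])
    out.name = "module"
    return out


def _merge_close_modules(labels: pd.Series, expr, merge_threshold: float) -> pd.Series:
    values = expr.values if hasattr(expr, "stage") else expr
    while True:
        mods = [m for m in labels.unique() if m != -1]
        if len(mods) < 2:
            return labels
        eigs = {}
        for m in mods:
            ids = labels.index[labels == m]
            eigs[m] = _first_pc(values.loc[ids].to_numpy(dtype=float))[0]
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = abs(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if r > 1.0 - merge_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels = labels.where(labels != b, other=a)


def _first_pc(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component across samples of row-standardized values.

    Returns (unit-norm eigengene over samples, variance explained); sign
    oriented so the eigengene correlates non-negatively with the mean
    standardized profile.
    """
    z, _ = _standardize_rows(values)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    return pc, var_explained


def module_eigengenes(
    expr, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (first PC, unit norm) per non-grey module.

    Returns (eigengenes: module x sample, variance explained per module).
    A size-1 module's eigengene is its standardized profile (warned).
    """
    values = expr.values if hasattr(expr, "stage") else expr
    rows, var_rows = {}, {}
    for m in labels.unique():
        if m == UNASSIGNED:
            continue
        ids = labels.index[labels == m]
        sub = values.loc[ids].to_numpy(dtype=float)
        if sub.shape[0] == 1:
            warnings.warn(f"module {m} has a single transcript")
            z, _ = _standardize_rows(sub)
            pc = z[0] / np.linalg.norm(z[0])
            var = 1.0
        else:
            pc, var = _first_pc(sub)
            pc = pc / np.linalg.norm(pc)
        rows[m] = pc
        var_rows[m] = var
    eig = pd.DataFrame(rows, index=values.columns).T
    return eig, pd.Series(var_rows, name="variance_explained")


def module_trait_correlation(
    eigengenes: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and two-sided p) of each eigengene against binary
    group-membership indicators and single-sample indicators."""
    traits = {}
    for g in expr_mod.GROUP_ORDER:
        if (samples["group"] == g).any():
            traits[g] = (samples["group"] == g).astype(float)
    for s in samples.index:
        traits[f"sample:{s}"] = pd.Series(
            (samples.index == s).astype(float), index=samples.index
        )
    trait_df = pd.DataFrame(traits).loc[eigengenes.columns]

    n = eigengenes.shape[1]
    r_rows, p_rows = {}, {}
    for m, eig in eigengenes.iterrows():
        e = eig.to_numpy(dtype=float)
        if np.std(e) == 0:
            raise ValueError(f"constant eigengene for module {m}")
        rs, ps = {}, {}
        for t in trait_df.columns:
            x = trait_df[t].to_numpy()
            r = float(np.corrcoef(e, x)[0, 1])
            # two-sided p via the t transform, expressed through the
            # beta distribution of r^2 (equivalent, avoids 0/0 at |r|=1)
            ps[t] = float(beta_dist.sf(r * r, 0.5, (n - 2) / 2.0)) if n > 2 else np.nan
            rs[t] = r
        r_rows[m], p_rows[m] = rs, ps
    return pd.DataFrame(r_rows).T, pd.DataFrame(p_rows).T


def eigengene_group_summaries(
    eigengenes: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Five-number summaries (median, quartiles, min, max) of each module's
    eigengene per experimental group — the boxplot export."""
    rows = []
    for m, eig in eigengenes.iterrows():
        for g in expr_mod.GROUP_ORDER:
            vals = eig[samples.index[samples["group"] == g]]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "module": m,
                    "group": g,
                    "median": float(vals.median()),
                    "q1": float(vals.quantile(0.25)),
                    "q3": float(vals.quantile(0.75)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)
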