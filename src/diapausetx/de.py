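"""Count-based differential expression: TMM normalization, negative-binomial
dispersion estimation, NB GLM likelihood-ratio tests, BH-FDR.

The model for transcript i in sample j is

    y_ij ~ NB(mu_ij, phi_i),   Var = mu + phi * mu^2,
    log mu_ij = beta_{i,g(j)} + log(N_j * f_j)

with group-mean design (EF/LF/EC/LC), library size N_j and TMM factor f_j
as offset.  The global test compares the 4-mean fit against a single mean
(df = 3); each pairwise test merges the two contrasted groups (df = 1).
Dispersions are gene-wise method-of-moments estimates shrunk toward a
trimmed common value; the shrinkage weight plays the role of a prior
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, rankdata

from . import expression as expr_mod

PAIRWISE_CONTRASTS = (
    ("EF", "LF"),
    ("EF", "EC"),
    ("EF", "LC"),
    ("LF", "EC"),
    ("LF", "LC"),
    ("EC", "LC"),
)

_MEAN_FLOOR = 1e-8
_PHI_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, multiply p_(k) by m/k, take the cumulative minimum from
    the largest rank down, cap at 1, restore input order.  NaNs are excluded
    and reinserted as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed, weighted mean of M-values of one sample against the reference.

    Doubly trimmed (30% on M, 5% on A) with inverse asymptotic-variance
    weights; returns the log2 scaling factor.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        raise ValueError("sample shares no expressed transcripts with the reference")
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method); weights are its inverse
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    Reference sample = the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    arr = counts.to_numpy(dtype=float)
    f75 = np.quantile(arr / libs[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = arr[:, ref_idx]
    log_factors = np.array(
        [_tmm_pair(arr[:, j], ref, libs[j], libs[ref_idx]) for j in range(arr.shape[1])]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Dispersion estimation


def _profile_common_dispersion(
    x: np.ndarray, sample_groups: pd.Series, group_sizes: pd.Series
) -> float:
    """Common NB dispersion by profile maximum likelihood.

    Group means are profiled out (the NB mean MLE is the sample mean for a
    shared mean on a common scale), leaving a 1-D likelihood in phi that is
    maximized by golden-section search on log phi.  A simple gene-wise
    moment average is biased low here — the sampling distribution of raw
    dispersion estimates at a handful of replicates is strongly
    right-skewed — whereas the pooled likelihood over thousands of genes
    is nearly unbiased.
    """
    masks = [(sample_groups == g).to_numpy() for g in group_sizes.index
             if group_sizes[g] >= 2]
    blocks = []
    for m in masks:
        xg = x[:, m]
        mu = xg.mean(axis=1)
        keep = mu > 0
        blocks.append((xg[keep], mu[keep], int(m.sum())))

    def negll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        total = 0.0
        for xg, mu, n_g in blocks:
            total += float(np.sum(_nb_loglik(xg, mu[:, None],
                                             np.full((xg.shape[0], 1), phi))))
            # Cox-Reid adjustment for the plug-in group means: without it
            # the profile likelihood is biased toward small dispersions
            info = n_g * mu / (1.0 + phi * mu)
            total -= 0.5 * float(np.sum(np.log(info)))
        return -total

    lo, hi = np.log(_PHI_FLOOR), np.log(5.0)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = negll(c), negll(d)
    for _ in range(60):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = negll(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = negll(d)
    return float(max(np.exp((a + b) / 2.0), _PHI_FLOOR))


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    prior_weight: float = 20.0,
) -> tuple[float, pd.Series]:
    """NB dispersions: profile-ML common value, moment-based gene-wise
    estimates shrunk toward it.

    Counts are scaled to a common effective library size; within-group
    sample variances in excess of the mean estimate phi * mu^2 per gene.
    The common dispersion maximizes the pooled profile likelihood; tagwise
    estimates are shrunk toward it with prior weight ``prior_weight``
    against the residual df of each gene.  Returns (common, per-transcript
    Series).
    """
    group_sizes = groups.value_counts()
    if (group_sizes < 2).all():
        raise ValueError("dispersion estimation needs replicates in some group")
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    eff = libs * factors.loc[counts.columns].to_numpy(dtype=float)
    scale = eff.mean() / eff
    x = counts.to_numpy(dtype=float) * scale[None, :]

    num = np.zeros(x.shape[0])
    den = np.zeros(x.shape[0])
    resid_df = 0
    for g in group_sizes.index:
        mask = (groups.loc[counts.columns] == g).to_numpy()
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        xg = x[:, mask]
        mean_g = xg.mean(axis=1)
        var_g = xg.var(axis=1, ddof=1)
        num += (n_g - 1) * (var_g - mean_g)
        den += (n_g - 1) * mean_g**2
        resid_df += n_g - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, 0.0, None)

    common = _profile_common_dispersion(x, groups.loc[counts.columns], group_sizes)

    tagwise = (prior_weight * common + resid_df * raw) / (prior_weight + resid_df)
    tagwise = np.clip(tagwise, _PHI_FLOOR, None)
    return common, pd.Series(tagwise, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM with group-mean design


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood. phi broadcasts per row."""
    mu = np.clip(mu, _MEAN_FLOOR, None)
    r = 1.0 / phi
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _fit_group_means(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, masks: list[np.ndarray],
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood group means for every transcript at once.

    For a log-link NB with a one-hot group design the IRLS normal equations
    decouple into one coefficient per group, each solved by damped Newton
    on the score  sum_j (y - mu) / (1 + phi mu).  Returns (betas
    [genes x groups], converged flags).
    """
    n_genes = y.shape[0]
    betas = np.empty((n_genes, len(masks)))
    converged = np.ones(n_genes, dtype=bool)
    exp_off = np.exp(offsets)
    for g, mask in enumerate(masks):
        yg = y[:, mask]
        og = exp_off[mask]
        tot = yg.sum(axis=1)
        beta = np.where(tot > 0, np.log(np.clip(tot, 1e-300, None) / og.sum()),
                        np.log(_MEAN_FLOOR))
        zero = tot == 0
        active = ~zero
        for _ in range(max_iter):
            mu = np.exp(beta[:, None]) * og[None, :]
            w = 1.0 + phi[:, None] * mu
            score = ((yg - mu) / w).sum(axis=1)
            info = (mu / w).sum(axis=1)
            step = np.where(info > 0, score / np.clip(info, 1e-12, None), 0.0)
            step = np.clip(step, -5.0, 5.0)
            beta = np.where(active, beta + step, beta)
            if np.max(np.abs(step[active])) < tol if active.any() else True:
                break
        else:
            mu = np.exp(beta[:, None]) * og[None, :]
            w = 1.0 + phi[:, None] * mu
            score = ((yg - mu) / w).sum(axis=1)
            converged &= np.abs(score) < 1e-4
        beta = np.where(zero, np.log(_MEAN_FLOOR), beta)
        betas[:, g] = beta
    return betas, converged


@dataclass
class DEResult:
    """Per-transcript statistics for one contrast."""

    contrast: str
    table: pd.DataFrame  # logFC, LR, df, p, fdr, direction
    factors: pd.Series = field(default=None, repr=False)
    effective_lib: pd.Series = field(default=None, repr=False)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["fdr"] <= self.table.attrs["alpha"]]


def lrt_contrast(
    counts: pd.DataFrame,
    groups: pd.Series,
    dispersions: pd.Series,
    factors: pd.Series,
    contrast: str | tuple[str, str],
    alpha: float = 0.05,
    group_order: tuple[str, ...] = expr_mod.GROUP_ORDER,
) -> DEResult:
    """Likelihood-ratio test of one contrast for every transcript.

    contrast = "global" tests any difference among the groups (df = k-1);
    a (a, b) pair merges those two groups under the reduced model (df = 1).
    log2FC is from fitted group means, first-named group in the numerator.
    """
    y = counts.to_numpy(dtype=float)
    sample_groups = groups.loc[counts.columns]
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    eff = libs * factors.loc[counts.columns].to_numpy(dtype=float)
    offsets = np.log(eff)
    phi = dispersions.loc[counts.index].to_numpy(dtype=float)

    present = [g for g in group_order if (sample_groups == g).any()]
    masks = [(sample_groups == g).to_numpy() for g in present]
    betas, conv = _fit_group_means(y, offsets, phi, masks)
    # mu_full per sample from its own group's beta
    group_idx = np.array([next(i for i, m in enumerate(masks) if m[j])
                          for j in range(y.shape[1])])
    mu_full = np.exp(betas[:, group_idx] + offsets[None, :])
    ll_full = _nb_loglik(y, mu_full, phi[:, None])

    if contrast == "global":
        merged = [np.ones(y.shape[1], dtype=bool)]
        betas_red, _ = _fit_group_means(y, offsets, phi, merged)
        mu_red = np.exp(betas_red[:, 0][:, None] + offsets[None, :])
        ll_red = _nb_loglik(y, mu_red, phi[:, None])
        df = len(present) - 1
        field_groups = [g for g in present if g.endswith("F")]
        culture_groups = [g for g in present if g.endswith("C")]
        b_field = betas[:, [present.index(g) for g in field_groups]].mean(axis=1)
        b_cult = betas[:, [present.index(g) for g in culture_groups]].mean(axis=1)
        logfc = (betas.max(axis=1) - betas.min(axis=1)) / np.log(2.0)
        direction_sign = b_field - b_cult
        label = "global"
    else:
        a, b = contrast
        if a not in present or b not in present:
            raise ValueError(f"unknown groups in contrast: {contrast}")
        ia, ib = present.index(a), present.index(b)
        pair_mask = masks[ia] | masks[ib]
        betas_pair, _ = _fit_group_means(y[:, pair_mask], offsets[pair_mask], phi,
                                         [np.ones(int(pair_mask.sum()), dtype=bool)])
        # reduced model differs from the full one only on the merged samples
        mu_red_pair = np.exp(betas_pair[:, 0][:, None] + offsets[pair_mask][None, :])
        ll_red = (
            ll_full
            - _nb_loglik(y[:, pair_mask], mu_full[:, pair_mask], phi[:, None])
            + _nb_loglik(y[:, pair_mask], mu_red_pair, phi[:, None])
        )
        df = 1
        logfc = (betas[:, ia] - betas[:, ib]) / np.log(2.0)
        direction_sign = logfc
        label = f"{a}v{b}"

    lr = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    p = chi2.sf(lr, df)
    all_zero = y.sum(axis=1) == 0
    p = np.where(all_zero, 1.0, p)
    lr = np.where(all_zero, 0.0, lr)
    logfc = np.where(all_zero, 0.0, logfc)
    p = np.where(conv, p, np.nan)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "LR": lr,
            "df": df,
            "p": p,
            "fdr": bh_adjust(p),
            "direction": np.where(direction_sign > 0, "up", "down"),
        },
        index=counts.index,
    )
    table.attrs["alpha"] = alpha
    return DEResult(label, table, factors=factors,
                    effective_lib=pd.Series(eff, index=counts.columns))


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int = 4,
    deg_definition: str = "global",
) -> tuple[dict[str, DEResult], frozenset]:
    """Full DE stage: cpm filter, TMM, dispersions, global + pairwise LRTs.

    Returns (results keyed by contrast label, DEG set).  The DEG set used
    downstream is the global-test significant set by default
    (``deg_definition='pairwise_union'`` switches to the union of pairwise
    significant sets).
    """
    groups = samples["group"]
    filtered = expr_mod.cpm_filter(counts, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    _, dispersions = estimate_dispersions(filtered, groups, factors)

    results: dict[str, DEResult] = {}
    results["global"] = lrt_contrast(filtered, groups, dispersions, factors,
                                     "global", alpha=alpha)
    present = set(groups.loc[filtered.columns])
    for a, b in PAIRWISE_CONTRASTS:
        if a in present and b in present:
            results[f"{a}v{b}"] = lrt_contrast(
                filtered, groups, dispersions, factors, (a, b), alpha=alpha
            )

    if deg_definition == "global":
        degs = frozenset(results["global"].significant)
    elif deg_definition == "pairwise_union":
        degs = frozenset().union(
            *(set(r.significant) for k, r in results.items() if k != "global")
        )
    else:
        raise ValueError(f"unknown deg_definition: {deg_definition!r}")
    return results, degs


def write_de_table(result: DEResult, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="transcript_id")
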