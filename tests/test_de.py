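"""Differential expression: BH step-up, TMM factors, dispersion recovery,
NB-GLM likelihood-ratio tests and the run_de orchestration."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diapausetx import de
from diapausetx import simulate as sim_mod


# ---------------------------------------------------------------------------
# BH adjustment


def bh_oracle(p):
    """Literal step-up definition, evaluated by brute force."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def test_bh_worked_example():
    out = de.bh_adjust(np.array([0.01, 0.02, 0.04, 0.5]))
    np.testing.assert_allclose(out, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_bruteforce_oracle(pvals):
    np.testing.assert_allclose(de.bh_adjust(np.array(pvals)), bh_oracle(pvals),
                               rtol=1e-12, atol=1e-15)


def test_bh_properties_and_missing():
    p = np.array([0.2, np.nan, 0.01, 0.7])
    out = de.bh_adjust(p)
    assert np.isnan(out[1])
    ok = ~np.isnan(p)
    assert (out[ok] >= p[ok] - 1e-15).all() and (out[ok] <= 1.0).all()
    same = np.full(5, 0.3)
    np.testing.assert_allclose(de.bh_adjust(same), same)
    with pytest.raises(ValueError):
        de.bh_adjust(np.array([1.2]))


# ---------------------------------------------------------------------------
# TMM


def _random_counts(seed, shape=(300, 6)):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.negative_binomial(5, 0.01, size=shape),
                          index=[f"t{i}" for i in range(shape[0])],
                          columns=[f"s{j}" for j in range(shape[1])])
    counts.iloc[:30, 0] *= 4  # composition shift in one library
    return counts


def test_tmm_identical_libraries_give_unit_factors():
    col = np.arange(1, 51)
    counts = pd.DataFrame({f"s{j}": col for j in range(4)})
    np.testing.assert_allclose(de.tmm_factors(counts), 1.0, atol=1e-12)


def test_tmm_depth_invariance():
    counts = _random_counts(8)
    base = de.tmm_factors(counts)
    doubled = counts.copy()
    doubled["s2"] = counts["s2"] * 2  # pure depth change, M-values invariant
    after = de.tmm_factors(doubled)
    # A-values and weights shift slightly with depth, so invariance is
    # approximate rather than exact
    assert abs(base["s2"] - after["s2"]) < 0.02


def test_tmm_geometric_mean_one():
    f = de.tmm_factors(_random_counts(9))
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_matches_edger_reference():
    """Independent cross-check against the Bioconductor implementation."""
    counts = _random_counts(5)
    mine = de.tmm_factors(counts)
    script = (
        "suppressMessages(library(edgeR));"
        "x <- matrix(scan('stdin', quiet=TRUE), ncol=6, byrow=TRUE);"
        "cat(paste(calcNormFactors(x, method='TMM'), collapse=','))"
    )
    proc = subprocess.run(
        ["Rscript", "-e", script],
        input="\n".join(" ".join(str(v) for v in row)
                        for row in counts.to_numpy()),
        capture_output=True, text=True, timeout=120,
    )
    assert proc.returncode == 0, proc.stderr
    theirs = np.array([float(v) for v in proc.stdout.strip().split(",")])
    np.testing.assert_allclose(mine.to_numpy(), theirs, atol=1e-10)


def test_tmm_needs_two_samples():
    with pytest.raises(ValueError):
        de.tmm_factors(pd.DataFrame({"s": [1, 2, 3]}))


# ---------------------------------------------------------------------------
# Dispersions


def _group_series(sample_table):
    return sample_table["group"]


def test_dispersion_poisson_counts_near_zero(sample_table):
    rng = np.random.default_rng(10)
    counts = pd.DataFrame(rng.poisson(100, size=(500, 16)),
                          index=[f"t{i}" for i in range(500)],
                          columns=sample_table.index)
    _, tagwise = de.estimate_dispersions(counts, _group_series(sample_table))
    assert float(tagwise.median()) <= 0.05


def test_dispersion_recovers_simulated_value(sample_table):
    rng = np.random.default_rng(11)
    phi = 0.2
    mu = 200.0
    lam = rng.gamma(1 / phi, phi * mu, size=(2000, 16))
    counts = pd.DataFrame(rng.poisson(lam), index=[f"t{i}" for i in range(2000)],
                          columns=sample_table.index)
    common, _ = de.estimate_dispersions(counts, _group_series(sample_table))
    assert common == pytest.approx(phi, abs=0.05)


def test_dispersion_shrinkage_limit(sample_table):
    counts = pd.DataFrame(
        np.random.default_rng(12).poisson(50, size=(100, 16)),
        index=[f"t{i}" for i in range(100)], columns=sample_table.index)
    common, tagwise = de.estimate_dispersions(
        counts, _group_series(sample_table), prior_weight=1e9)
    # up to the dispersion floor, all tagwise values collapse onto common
    np.testing.assert_allclose(tagwise, common, rtol=1e-3)


def test_dispersion_requires_replicates():
    counts = pd.DataFrame([[1, 2], [3, 4]], columns=["a", "b"])
    groups = pd.Series({"a": "EF", "b": "LC"})
    with pytest.raises(ValueError):
        de.estimate_dispersions(counts, groups)


# ---------------------------------------------------------------------------
# LRT


def _null_de():
    counts, _, samples, _ = sim_mod.generate_dataset(sim_mod.null_config(seed=1))
    return counts, samples


def test_lrt_recovers_planted_fold_change(sample_table):
    rng = np.random.default_rng(13)
    phi = 0.1
    mu = np.full((300, 16), 100.0)
    field = sample_table["source"].to_numpy() == "field"
    mu[:30, field] *= 4.0  # planted log2FC = +2 in field, 10% of genes
    counts = pd.DataFrame(rng.poisson(rng.gamma(1 / phi, phi * mu)),
                          index=[f"t{i}" for i in range(300)],
                          columns=sample_table.index)
    groups = sample_table["group"]
    factors = de.tmm_factors(counts)
    _, disp = de.estimate_dispersions(counts, groups, factors)
    res = de.lrt_contrast(counts, groups, disp, factors, ("EF", "EC"))
    planted = res.table.iloc[:30]
    assert float(np.median(planted["logFC"])) == pytest.approx(2.0, abs=0.5)
    assert (planted["direction"] == "up").mean() > 0.95


def test_lrt_all_zero_transcript_policy():
    counts, samples = _null_de()
    counts.iloc[0] = 0
    results, _ = de.run_de(counts, samples, min_cpm=0, min_samples=0)
    assert results["global"].table["p"].iloc[0] == 1.0
    assert results["global"].table["logFC"].iloc[0] == 0.0


def test_lrt_sample_order_invariance():
    counts, samples = _null_de()
    counts = counts.iloc[:200]
    groups = samples["group"]
    factors = de.tmm_factors(counts)
    _, disp = de.estimate_dispersions(counts, groups, factors)
    a = de.lrt_contrast(counts, groups, disp, factors, "global").table
    perm = list(np.random.default_rng(14).permutation(counts.columns))
    b = de.lrt_contrast(counts[perm], groups, disp, factors, "global").table
    np.testing.assert_allclose(a["LR"], b["LR"], rtol=1e-8, atol=1e-10)


def test_lrt_merged_identical_groups_near_zero(sample_table):
    # duplicate one group's counts into another: pairwise LRT ~ 0
    rng = np.random.default_rng(15)
    base = rng.poisson(80, size=(100, 4))
    counts = pd.DataFrame(
        np.hstack([base, base, rng.poisson(80, size=(100, 8))]),
        index=[f"t{i}" for i in range(100)], columns=sample_table.index)
    groups = sample_table["group"]
    factors = pd.Series(1.0, index=counts.columns)
    _, disp = de.estimate_dispersions(counts, groups, factors)
    res = de.lrt_contrast(counts, groups, disp, factors, ("EF", "LF"))
    assert float(res.table["LR"].max()) < 1e-6


def test_lrt_single_gene_matches_statsmodels(sample_table):
    """Dual-route check of the NB GLM fit against statsmodels."""
    import statsmodels.api as sm

    rng = np.random.default_rng(16)
    y = rng.poisson(rng.gamma(10, 10, size=16))
    # a large constant gene keeps the library offsets non-degenerate
    counts = pd.DataFrame([y, np.full(16, 10_000)], index=["t0", "pad"],
                          columns=sample_table.index)
    groups = sample_table["group"]
    phi = pd.Series([0.1, 0.1], index=["t0", "pad"])
    factors = pd.Series(1.0, index=counts.columns)
    res = de.lrt_contrast(counts, groups, phi, factors, "global")

    design = pd.get_dummies(groups).to_numpy(dtype=float)
    offset = np.log(counts.sum(axis=0).to_numpy(dtype=float))
    full = sm.GLM(y, design, family=sm.families.NegativeBinomial(alpha=0.1),
                  offset=offset).fit()
    red = sm.GLM(y, np.ones((16, 1)),
                 family=sm.families.NegativeBinomial(alpha=0.1),
                 offset=offset).fit()
    lr_sm = 2 * (full.llf - red.llf)
    assert float(res.table["LR"].iloc[0]) == pytest.approx(lr_sm, abs=1e-4)


def test_run_de_up_down_identity_and_df(default_de):
    results, _ = default_de
    assert results["global"].table["df"].iloc[0] == 3
    for label, res in results.items():
        if label == "global":
            continue
        assert res.table["df"].iloc[0] == 1
        sig = res.table[res.table["fdr"] <= 0.05]
        n_up = int((sig["direction"] == "up").sum())
        n_down = int((sig["direction"] == "down").sum())
        assert n_up + n_down == len(sig)


def test_run_de_null_deg_count_bounded():
    from scipy.stats import binom

    counts, samples = _null_de()
    results, degs = de.run_de(counts, samples)
    m = len(results["global"].table)
    # BH at 0.05 on a global null: false rejections are far below the
    # raw-alpha binomial bound
    bound = binom.ppf(0.99, m, 0.05)
    assert len(degs) <= bound


def test_run_de_deg_definitions(default_dataset):
    _, counts, _, samples, _ = default_dataset
    _, global_degs = de.run_de(counts, samples)
    _, union_degs = de.run_de(counts, samples, deg_definition="pairwise_union")
    assert len(global_degs) > 0 and len(union_degs) > 0
    with pytest.raises(ValueError):
        de.run_de(counts, samples, deg_definition="nope")
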