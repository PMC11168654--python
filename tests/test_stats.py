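from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from beescore import (
    classify_performers,
    distribution_summary,
    group_learning_curves,
    hierarchical_regression,
    lilliefors_statistic,
    lilliefors_test,
    mann_whitney,
    score_cohort,
    spearman_matrix,
    wilcoxon_matched_pairs,
)


def scores_frame(pscores, **extra):
    n = len(pscores)
    df = pd.DataFrame({
        "bee_id": [f"b{i:03d}" for i in range(n)],
        "Pscore": pscores,
    })
    for k, v in extra.items():
        df[k] = v
    return df


# --- classification ----------------------------------------------------

def test_threshold_boundary_is_high():
    scores = scores_frame([2.6, 2.59, 0.0, 6.0])
    lab = classify_performers(scores)
    assert list(lab.labels) == ["high", "low", "low", "high"]
    assert lab.n_high + lab.n_low == 4


def test_all_zero_cohort_all_low():
    lab = classify_performers(scores_frame([0.0] * 10))
    assert lab.n_low == 10


def test_degenerate_bees_classify_as_expected(perfect_bee, zero_bee):
    both = pd.concat([perfect_bee, zero_bee.assign(bee_id="bee_002")])
    lab = classify_performers(score_cohort(both))
    assert dict(lab.labels) == {"bee_001": "high", "bee_002": "low"}


def test_threshold_override():
    scores = scores_frame([2.8, 3.2])
    lab = classify_performers(scores, threshold=3.0)
    assert list(lab.labels) == ["low", "high"]


# --- distribution summary ----------------------------------------------

def test_summary_mean_sd_exact():
    s = distribution_summary([0.0, 3.0, 6.0], n_mc=100, seed=0)
    assert s.mean == 3.0
    assert s.sd == 3.0
    assert sum(s.fractions) == pytest.approx(1.0)


def test_summary_needs_three():
    with pytest.raises(ValueError):
        distribution_summary([1.0, 2.0])


def test_normal_sample_band_fraction():
    """For Gaussian data about 68.3% of a sample falls within one
    sample SD of the sample mean."""
    fracs = []
    for seed in range(50):
        x = np.random.default_rng(seed).standard_normal(171)
        s = distribution_summary(x, n_mc=50, seed=seed)
        fracs.append(s.fractions[1])
    assert abs(np.mean(fracs) - 0.683) < 0.02


# --- Lilliefors ---------------------------------------------------------

def grid_oracle_lilliefors(x, n_grid=200001):
    x = np.sort(np.asarray(x, float))
    mu, sd = x.mean(), x.std(ddof=1)
    grid = np.linspace(x.min() - 4 * sd, x.max() + 4 * sd, n_grid)
    ecdf = np.searchsorted(x, grid, side="right") / len(x)
    diff = np.abs(ecdf - sps.norm.cdf((grid - mu) / sd))
    return diff.max()


def test_statistic_matches_grid_oracle():
    x = np.arange(1, 21) * 1.7 + 3
    d = lilliefors_statistic(x)
    assert d == pytest.approx(grid_oracle_lilliefors(x), abs=1e-3)


def test_statistic_matches_statsmodels():
    from statsmodels.stats.diagnostic import lilliefors as sm_lf
    x = np.random.default_rng(4).gamma(2, size=60)
    d_sm, _ = sm_lf(x, dist="norm", pvalmethod="table")
    assert lilliefors_statistic(x) == pytest.approx(d_sm, abs=1e-12)


def test_small_or_constant_samples_rejected():
    with pytest.raises(ValueError):
        lilliefors_test([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        lilliefors_test([2.0] * 10)


def test_null_pvalues_are_uniform():
    """Under Gaussian data the Monte-Carlo p-value is uniform."""
    rng = np.random.default_rng(8)
    pvals = [lilliefors_test(rng.standard_normal(25),
                             n_mc=999, seed=seed)[1]
             for seed in range(200)]
    ks_p = sps.kstest(pvals, "uniform").pvalue
    assert ks_p > 0.001


def test_seeded_pvalue_reproducible():
    x = np.random.default_rng(3).standard_normal(40)
    assert lilliefors_test(x, seed=5) == lilliefors_test(x, seed=5)


# --- Mann-Whitney -------------------------------------------------------

def test_complete_separation_gives_u_zero():
    u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert z < 0 or p < 1


def test_identical_groups_give_z_zero():
    u, z, p = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
    assert z == 0.0
    assert p == 1.0


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def exact_mw_pvalue(a, b):
    """Two-sided p by full enumeration of all C(n1+n2, n1) labelings."""
    pooled = np.asarray(list(a) + list(b), float)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    mu = n1 * (len(pooled) - n1) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = [u_of(idx) for idx in combinations(range(len(pooled)), n1)]
    dev = abs(u_obs - mu)
    return np.mean([abs(u - mu) >= dev - 1e-12 for u in us])


def test_mann_whitney_against_exact_enumeration():
    a, b = [1, 3, 5, 7], [2, 4, 6, 8]
    u, z, p = mann_whitney(a, b)
    # U statistic agrees with the pair-count definition
    u_pairs = sum(x > y for x in a for y in b)
    assert u == min(u_pairs, len(a) * len(b) - u_pairs)
    p_exact = exact_mw_pvalue(a, b)
    # the normal approximation is crude at n=8; the exact enumeration
    # is the reference and is itself cross-checked against scipy
    assert abs(p - p_exact) < 0.15
    u_sp, p_sp = sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="exact")
    assert p_exact == pytest.approx(p_sp)


def test_mann_whitney_matches_scipy_with_ties():
    rng = np.random.default_rng(21)
    a = rng.integers(0, 5, 30).astype(float)
    b = rng.integers(1, 6, 25).astype(float)
    _, z, p = mann_whitney(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    assert p == pytest.approx(res.pvalue, rel=1e-9)


# --- Wilcoxon -----------------------------------------------------------

def test_one_sided_shift_gives_t_zero():
    x = np.arange(10.0)
    t, z, p = wilcoxon_matched_pairs(x + 1, x)
    assert t == 0.0


def test_single_nonzero_difference():
    x = [1.0, 2.0, 3.0]
    y = [1.0, 2.0, 4.0]
    t, z, p = wilcoxon_matched_pairs(x, y)
    assert t == 0.0


def test_all_zero_differences_rejected():
    with pytest.raises(ValueError):
        wilcoxon_matched_pairs([1.0, 2.0], [1.0, 2.0])


def exact_wilcoxon_pvalue(d):
    """Two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = len(d) * (len(d) + 1) / 4.0
    devs = []
    for signs in product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, bool)].sum()
        devs.append(abs(w - mu) >= abs(w_obs - mu) - 1e-12)
    return np.mean(devs)


def test_wilcoxon_against_exact_sign_flip_enumeration():
    rng = np.random.default_rng(6)
    x = rng.normal(0.8, 1, 6)
    y = rng.normal(0, 1, 6)
    t, z, p = wilcoxon_matched_pairs(x, y)
    p_exact = exact_wilcoxon_pvalue(x - y)
    assert abs(p - p_exact) < 0.15
    res = sps.wilcoxon(x, y, mode="exact")
    assert t == res.statistic
    assert p_exact == pytest.approx(res.pvalue)


# --- Spearman -----------------------------------------------------------

def test_spearman_diagonal_and_monotone():
    df = pd.DataFrame({"a": [1, 2, 3, 4, 5],
                       "b": [10, 8, 6, 4, 2],
                       "c": [2, 4, 6, 8, 10]})
    rho, p = spearman_matrix(df, ["a", "b", "c"])
    assert rho.loc["a", "a"] == 1.0
    assert rho.loc["a", "b"] == pytest.approx(-1.0)
    assert rho.loc["a", "c"] == pytest.approx(1.0)
    assert np.allclose(rho, rho.T)


def test_spearman_with_ties_matches_rank_formula():
    df = pd.DataFrame({"x": [1, 2, 2, 3, 3], "y": [5, 5, 4, 4, 1]})
    rho, _ = spearman_matrix(df, ["x", "y"])
    rx = sps.rankdata(df["x"])
    ry = sps.rankdata(df["y"])
    manual = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (
        rx.std() * ry.std())
    assert rho.loc["x", "y"] == pytest.approx(manual)
    assert rho.loc["x", "y"] == pytest.approx(
        sps.spearmanr(df["x"], df["y"]).statistic)


def test_constant_variable_reported_missing():
    df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 2, 2, 2]})
    rho, _ = spearman_matrix(df, ["x", "y"])
    assert np.isnan(rho.loc["x", "y"])
    assert rho.loc["y", "y"] == 1.0


# --- hierarchical regression -------------------------------------------

def make_scored(n=60, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.integers(0, 6, size=(n, 6)) / 5.0,
        columns=["Acq1", "Acq2", "DisCond1", "DisCond2", "DisT12",
                 "DisT34"],
    )
    df["Pscore"] = df.sum(axis=1)
    df.insert(0, "bee_id", [f"b{i}" for i in range(n)])
    return df


def test_saturated_sum_reaches_exact_unity():
    res = hierarchical_regression(make_scored())
    assert res.final_r2 == 1.0
    assert sum(s.r2_change for s in res.steps) == pytest.approx(1.0,
                                                                abs=1e-9)
    assert np.isnan(res.steps[-1].f_change)
    assert np.isnan(res.steps[-1].p)
    assert all(s.p < 0.05 for s in res.steps[:-1])
    r2s = [s.r2 for s in res.steps]
    assert all(b >= a for a, b in zip(r2s, r2s[1:]))


def test_orthogonal_first_predictor_gives_zero_step1():
    rng = np.random.default_rng(5)
    n = 40
    x1 = np.tile([1.0, -1.0], n // 2)
    y = rng.normal(size=n)
    y = y - y.mean() - (y @ x1) / (x1 @ x1) * x1  # exactly orthogonal
    df = pd.DataFrame({"bee_id": range(n), "x1": x1,
                       "x2": rng.normal(size=n), "y": y})
    res = hierarchical_regression(df, order=("x1", "x2"), response="y")
    assert res.steps[0].r2 < 1e-10


def test_r2_path_matches_normal_equations_oracle():
    rng = np.random.default_rng(17)
    n = 8
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 1.0 + 2 * x1 - x2 + rng.normal(size=n)
    df = pd.DataFrame({"bee_id": range(n), "x1": x1, "x2": x2, "y": y})
    res = hierarchical_regression(df, order=("x1", "x2"), response="y")

    def oracle_r2(X):
        D = np.column_stack([np.ones(n), X])
        beta = np.linalg.inv(D.T @ D) @ D.T @ y
        resid = y - D @ beta
        return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    assert res.steps[0].r2 == pytest.approx(oracle_r2(x1[:, None]))
    assert res.steps[1].r2 == pytest.approx(
        oracle_r2(np.column_stack([x1, x2])))


def test_regression_invariances():
    df = make_scored(seed=3)
    base = hierarchical_regression(df)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    perm = hierarchical_regression(shuffled)
    assert [s.r2 for s in perm.steps] == pytest.approx(
        [s.r2 for s in base.steps])
    rescaled = df.copy()
    rescaled["Acq1"] = rescaled["Acq1"] * 37.0
    scaled = hierarchical_regression(rescaled)
    assert [s.r2 for s in scaled.steps] == pytest.approx(
        [s.r2 for s in base.steps])


def test_rank_deficiency_names_the_step():
    df = make_scored(seed=9)
    df["Acq2"] = df["Acq1"]
    with pytest.raises(ValueError, match="step 2"):
        hierarchical_regression(df)


def test_too_few_rows_rejected():
    with pytest.raises(ValueError):
        hierarchical_regression(make_scored(n=7))


# --- learning curves ----------------------------------------------------

def test_curves_all_one_cohort(protocol1):
    from .conftest import bee_table_from
    bees = pd.concat(
        [bee_table_from(protocol1, lambda ev: 1, bee_id=f"b{i}")
         for i in range(3)])
    curves = group_learning_curves(bees)
    assert (curves["percent"] == 100.0).all()
    assert len(curves) == 56


def test_curves_single_bee_binary(perfect_bee):
    curves = group_learning_curves(perfect_bee)
    assert set(curves["percent"]).issubset({0.0, 100.0})


def test_curves_perfect_learners_step_function(perfect_bee):
    curves = group_learning_curves(perfect_bee)
    cond = curves[(curves["block"] == "conditioning")
                  & (curves["stimulus_role"] == "CSplus")
                  & (curves["phase"] == 1)].sort_values("event_index")
    assert list(cond["percent"]) == [0.0, 100, 100, 100, 100, 100]
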