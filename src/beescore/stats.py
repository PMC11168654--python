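"""Cohort-level statistics for the individualized performance score.

Implements the battery applied to a scored cohort: high/low performer
classification at a P-score threshold, a distribution summary with a
Monte-Carlo Lilliefors normality test, tie-corrected Mann-Whitney U and
Wilcoxon matched-pairs tests, a Spearman rank-correlation matrix, the
hierarchical (sequential) OLS decomposition of P-score variance, and
tidy group learning curves for plotting or export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import SCORE_COLUMNS

DEFAULT_THRESHOLD = 2.6

HIERARCHY_ORDER = tuple(SCORE_COLUMNS)


@dataclass(frozen=True)
class PerformerLabeling:
    threshold: float
    labels: pd.Series  # index = bee_id, values in {"high", "low"}

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def classify_performers(
    scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> PerformerLabeling:
    """Label each bee high (P-score >= threshold) or low (< threshold)."""
    labels = pd.Series(
        np.where(scores["Pscore"].to_numpy() >= threshold, "high", "low"),
        index=pd.Index(scores["bee_id"], name="bee_id"),
        name="performer",
    )
    return PerformerLabeling(threshold=threshold, labels=labels)


def lilliefors_statistic(sample) -> float:
    """Kolmogorov-Smirnov sup-distance to the fitted normal CDF."""
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    cdf = sps.norm.cdf((x - mu) / sd)
    d_plus = (np.arange(1, n + 1) / n - cdf).max()
    d_minus = (cdf - np.arange(0, n) / n).max()
    return float(max(d_plus, d_minus))


def lilliefors_test(
    sample, n_mc: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The statistic is the KS distance between the empirical CDF and a
    normal CDF with mean/SD estimated from the same sample.  The
    p-value is the add-one upper-tail frequency of the statistic among
    ``n_mc`` standard-normal samples of the same size run through the
    identical estimator, which is exact in distribution at any n
    (location/scale estimation makes the null distribution
    parameter-free).
    """
    x = np.asarray(sample, float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    d_obs = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_mc, len(x)))
    null_mu = null.mean(axis=1, keepdims=True)
    null_sd = null.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((null - null_mu) / null_sd, axis=1)
    cdf = sps.norm.cdf(z)
    grid_hi = np.arange(1, len(x) + 1) / len(x)
    grid_lo = np.arange(0, len(x)) / len(x)
    d_null = np.maximum((grid_hi - cdf).max(axis=1),
                        (cdf - grid_lo).max(axis=1))
    p = (1.0 + (d_null >= d_obs).sum()) / (n_mc + 1.0)
    return d_obs, float(p)


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    n_below: int   # P-score <= mean - SD
    n_within: int  # strictly between the band edges
    n_above: int   # P-score >= mean + SD
    lilliefors_D: float
    lilliefors_p: float

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.n_below / self.n, self.n_within / self.n,
                self.n_above / self.n)


def distribution_summary(
    scores, n_mc: int = 10000, seed: int = 0
) -> DistributionSummary:
    """Mean, sample SD, +/-1 SD band counts and Lilliefors test.

    ``scores`` is a sequence of P-scores or a scored-cohort frame with
    a ``Pscore`` column.  Band edges follow the study's reading: the
    lower and upper tails include their edge values.
    """
    if isinstance(scores, pd.DataFrame):
        x = scores["Pscore"].to_numpy(float)
    else:
        x = np.asarray(scores, float)
    if len(x) < 3:
        raise ValueError("need at least 3 scores")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    lo, hi = mean - sd, mean + sd
    n_below = int((x <= lo).sum())
    n_above = int((x >= hi).sum())
    try:
        d, p = lilliefors_test(x, n_mc=n_mc, seed=seed)
    except ValueError:  # n < 5 or constant: test undefined
        d, p = float("nan"), float("nan")
    return DistributionSummary(
        n=len(x), mean=mean, sd=sd, n_below=n_below,
        n_within=len(x) - n_below - n_above, n_above=n_above,
        lilliefors_D=d, lilliefors_p=p,
    )


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float((counts**3 - counts).sum())


def mann_whitney(group_a, group_b) -> tuple[float, float, float]:
    """Mann-Whitney U with midranks and tie-corrected normal Z.

    Returns ``(U, Z, p)`` where U is the smaller of the two U
    statistics, Z is signed (positive when group A ranks above group
    B), and p is the two-sided normal-approximation p-value without
    continuity correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var == 0:
        return float(u), 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


def wilcoxon_matched_pairs(x, y) -> tuple[float, float, float]:
    """Wilcoxon matched-pairs signed-rank test, zeros dropped.

    Returns ``(T, Z, p)``: T is the smaller signed-rank sum, Z the
    tie-corrected normal deviate (signed, positive when x tends to
    exceed y), p two-sided without continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    t = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var == 0:
        return float(t), 0.0, 1.0
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(t), float(z), float(min(p, 1.0))


def spearman_matrix(
    scores: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations between score variables.

    Computed as Pearson correlation on midranks.  Returns ``(rho, p)``
    frames; a constant variable yields NaN against every other (its
    diagonal stays 1).  p-values use the t approximation with n-2 df.
    """
    if variables is None:
        variables = list(SCORE_COLUMNS) + ["Pscore"]
    data = scores[variables].to_numpy(float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 bees per pair")
    ranked = np.apply_along_axis(sps.rankdata, 0, data)
    sd = ranked.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranked, rowvar=False)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pmat = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pmat, 0.0)
    idx = pd.Index(variables)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(pmat, index=idx, columns=idx))


@dataclass(frozen=True)
class RegressionStep:
    variable: str
    r2: float
    r2_change: float
    f_change: float  # NaN when the model is saturated
    df: tuple[int, int]
    p: float         # NaN when the model is saturated


@dataclass(frozen=True)
class HierRegressionResult:
    steps: tuple[RegressionStep, ...]
    beta: dict  # standardized coefficients from the full model
    n: int

    @property
    def final_r2(self) -> float:
        return self.steps[-1].r2


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = ((y - y.mean())**2).sum()
    if sst == 0:
        raise ValueError("response is constant")
    r2 = 1.0 - (resid**2).sum() / sst
    # snap to the saturation boundary: residuals at rounding level mean
    # the model is exact (the P-score is an exact sum of its parts)
    if r2 > 1.0 - 1e-10:
        return 1.0
    return max(r2, 0.0)


def hierarchical_regression(
    scores: pd.DataFrame,
    order: tuple[str, ...] = HIERARCHY_ORDER,
    response: str = "Pscore",
) -> HierRegressionResult:
    """Sequential OLS decomposition of the response variance.

    Predictors enter one at a time in ``order``; at each step k the
    model is refit on the first k predictors and the increment
    ``R2_k - R2_{k-1}`` is attributed to the entering variable, with an
    F-change statistic on (1, n-k-1) degrees of freedom.  When a step
    reaches R2 = 1 exactly (the response is an exact function of the
    included predictors) its F and p are reported as NaN — the change
    statistic is undefined at saturation.  Standardized betas come from
    the single full model fit on z-scored variables.
    """
    y = scores[response].to_numpy(float)
    n = len(y)
    if n <= len(order) + 1:
        raise ValueError("need n > number of predictors + 1")
    X_full = scores[list(order)].to_numpy(float)

    steps = []
    prev_r2 = 0.0
    for k in range(1, len(order) + 1):
        Xk = X_full[:, :k]
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xk]))
        if rank < k + 1:
            raise ValueError(
                f"rank-deficient design at step {k} ({order[k-1]!r})")
        r2 = _r2(Xk, y)
        dr2 = r2 - prev_r2
        df2 = n - k - 1
        if r2 >= 1.0:
            f_change, p = float("nan"), float("nan")
        else:
            f_change = dr2 * df2 / (1.0 - r2)
            p = float(sps.f.sf(f_change, 1, df2))
        steps.append(RegressionStep(order[k - 1], r2, dr2, f_change,
                                    (1, df2), p))
        prev_r2 = r2

    zX = (X_full - X_full.mean(axis=0)) / X_full.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    coef, _, _, _ = np.linalg.lstsq(
        np.column_stack([np.ones(n), zX]), zy, rcond=None)
    beta = dict(zip(order, coef[1:]))
    return HierRegressionResult(steps=tuple(steps), beta=beta, n=n)


def group_learning_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Percent of bees responding per protocol event (tidy summary).

    One row per (phase, block, stimulus_role, concentration,
    event_index) with the number of bees, responders and percent
    responding — the group acquisition and retention curves.
    """
    grouped = (
        table.groupby(["phase", "block", "stimulus_role", "concentration",
                       "event_index"], sort=True)["response"]
        .agg(n_bees="size", n_responding="sum")
        .reset_index()
    )
    grouped["percent"] = 100.0 * grouped["n_responding"] / grouped["n_bees"]
    return grouped
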