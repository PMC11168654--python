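"""End-to-end analysis report for a scored cohort.

Bundles the full statistical battery into one JSON-serializable dict so
the CLI and scripted pipelines share a single code path.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import pandas as pd

from . import stats as st
from .contingency import build_phase_contingency, g_test_2x2
from .scoring import SCORE_COLUMNS, score_cohort


def _nan_to_none(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def analyze_cohort(
    table: pd.DataFrame,
    threshold: float = st.DEFAULT_THRESHOLD,
    lilliefors_mc: int = 10000,
    seed: int = 0,
) -> dict:
    """Score a response table and run the full statistical battery.

    Returns a dict with keys ``scores`` (DataFrame), ``labels``
    (Series), ``curves`` (DataFrame) and ``stats`` (JSON-ready dict
    holding the distribution summary, high/low Mann-Whitney tests per
    variable, phase Wilcoxon comparisons, phase G-tests, the Spearman
    matrix and the hierarchical regression).
    """
    scores = score_cohort(table)
    labeling = st.classify_performers(scores, threshold=threshold)
    curves = st.group_learning_curves(table)
    notices: list[str] = []

    report: dict = {
        "n_bees": int(len(scores)),
        "threshold": threshold,
        "n_high": labeling.n_high,
        "n_low": labeling.n_low,
    }

    try:
        summary = st.distribution_summary(
            scores, n_mc=lilliefors_mc, seed=seed)
        report["distribution"] = {
            "n": summary.n, "mean": summary.mean, "sd": summary.sd,
            "n_below_1sd": summary.n_below,
            "n_within_1sd": summary.n_within,
            "n_above_1sd": summary.n_above,
            "lilliefors_D": summary.lilliefors_D,
            "lilliefors_p": summary.lilliefors_p,
        }
    except ValueError as err:
        notices.append(f"distribution summary skipped: {err}")
        report["distribution"] = None

    high = scores[labeling.labels.loc[scores["bee_id"]].values == "high"]
    low = scores[labeling.labels.loc[scores["bee_id"]].values == "low"]
    mw = {}
    if len(high) and len(low):
        for var in SCORE_COLUMNS + ["control_responses"]:
            u, z, p = st.mann_whitney(high[var], low[var])
            mw[var] = {
                "mean_high": float(high[var].mean()),
                "mean_low": float(low[var].mean()),
                "U": u, "Z": z, "p": p,
            }
    else:
        notices.append("high/low group tests skipped: one group is "
                       "empty at this threshold")
    report["mann_whitney_high_vs_low"] = mw

    wilcoxon = {}
    for name, (x, y) in {
        "DisCond1_vs_DisCond2": (scores["DisCond1"], scores["DisCond2"]),
        "DisT12_vs_DisT34": (scores["DisT12"], scores["DisT34"]),
        "Acq1_vs_Acq2": (scores["Acq1"], scores["Acq2"]),
    }.items():
        try:
            t, z, p = st.wilcoxon_matched_pairs(x, y)
            wilcoxon[name] = {"T": t, "Z": z, "p": p}
        except ValueError as err:
            wilcoxon[name] = {"skipped": str(err)}
    report["wilcoxon_phase_comparisons"] = wilcoxon

    g_tests = {}
    for role in ("CSplus", "CSminus"):
        for scope in ("conditioning", "retention_pairs"):
            tab = build_phase_contingency(table, role, scope)
            try:
                g, df, p = g_test_2x2(tab)
                g_tests[f"{role}_{scope}"] = {
                    "table": [[tab.a, tab.b], [tab.c, tab.d]],
                    "G": g, "df": df, "p": p,
                }
            except ValueError as err:
                g_tests[f"{role}_{scope}"] = {
                    "table": [[tab.a, tab.b], [tab.c, tab.d]],
                    "skipped": str(err),
                }
    report["g_tests_phase1_vs_phase2"] = g_tests

    try:
        rho, pmat = st.spearman_matrix(scores)
        report["spearman"] = {
            "variables": list(rho.columns),
            "rho": [[_nan_to_none(v) for v in row]
                    for row in rho.to_numpy()],
            "p": [[_nan_to_none(v) for v in row]
                  for row in pmat.to_numpy()],
        }
    except ValueError as err:
        notices.append(f"correlation matrix skipped: {err}")
        report["spearman"] = None

    try:
        reg = st.hierarchical_regression(scores)
        report["hierarchical_regression"] = {
            "n": reg.n,
            "steps": [
                {k: _nan_to_none(v) for k, v in asdict(s).items()}
                for s in reg.steps
            ],
            "final_r2": reg.final_r2,
            "beta": {k: float(v) for k, v in reg.beta.items()},
        }
    except ValueError as err:
        notices.append(f"hierarchical regression skipped: {err}")
        report["hierarchical_regression"] = None

    if notices:
        report["notices"] = notices
    return {"scores": scores, "labels": labeling.labels,
            "curves": curves, "stats": report}
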