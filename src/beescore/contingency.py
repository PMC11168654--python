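"""2x2 contingency statistics, phase contrasts and gene-list overlap.

The G-test (likelihood-ratio chi-square, ``G = 2 sum O ln(O/E)``) and
the Pearson chi-square are computed without Yates or Williams
corrections; the phase contrast builds the response/non-response tables
the G-test consumes from a scored cohort, and the overlap test asks
whether two gene lists share more members than expected by chance in a
finite genome (13,440 annotated genes for the honeybee microarray
platform).  The 2^-ddCt fold change for relative qPCR quantification is
included for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

HONEYBEE_GENOME_SIZE = 13440


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = conditions, cols = yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("grand total must be >= 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], float)

    @property
    def margins(self) -> tuple[float, float, float, float]:
        m = self.matrix
        return (m[0].sum(), m[1].sum(), m[:, 0].sum(), m[:, 1].sum())


def _check_margins(table: ContingencyTable2x2) -> None:
    if any(m == 0 for m in table.margins):
        raise ValueError("all row and column margins must be positive")


def g_test_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Likelihood-ratio test of independence; returns (G, df=1, p).

    ``G = 2 sum O ln(O/E)`` over the four cells with independence
    expectations; empty cells contribute zero; no continuity or
    Williams correction; p from chi-square with 1 df.
    """
    _check_margins(table)
    obs = table.matrix
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = obs > 0
    g = 2.0 * (obs[mask] * np.log(obs[mask] / exp[mask])).sum()
    return float(g), 1, float(sps.chi2.sf(g, 1))


def chi2_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square of independence, uncorrected; (chi2, df=1, p)."""
    _check_margins(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2, c1, c2 = table.margins
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), 1, float(sps.chi2.sf(chi2, 1))


def build_phase_contingency(
    table: pd.DataFrame, stimulus_role: str, scope: str = "conditioning"
) -> ContingencyTable2x2:
    """Phase-1 vs phase-2 response counts for one stimulus role.

    ``scope='conditioning'`` counts responses to the role over scored
    conditioning trials 2-6 (5 presentations per bee per phase, the
    same window the behavioral variables use); ``scope='retention_pairs'``
    counts over the 6 odor presentations of a phase's two retention
    sets.  Rows are (phase 1, phase 2), columns (responses,
    non-responses).
    """
    if stimulus_role not in ("CSplus", "CSminus"):
        raise ValueError("stimulus_role must be CSplus or CSminus")
    if scope == "conditioning":
        sub = table[(table["block"] == "conditioning")
                    & (table["stimulus_role"] == stimulus_role)]
        # trial number within the alternating schedule; trial 1 unscored
        trial = (sub["event_index"] + 1) // 2
        sub = sub[trial >= 2]
        expected_per_bee = 5
    elif scope == "retention_pairs":
        sub = table[table["block"].isin(["retention1", "retention2"])
                    & (table["stimulus_role"] == stimulus_role)]
        expected_per_bee = 6
    else:
        raise ValueError("scope must be 'conditioning' or 'retention_pairs'")

    counts = []
    for phase in (1, 2):
        ph = sub[sub["phase"] == phase]
        per_bee = ph.groupby("bee_id").size()
        if (per_bee != expected_per_bee).any():
            bad = per_bee.index[per_bee != expected_per_bee].tolist()
            raise ValueError(f"incomplete bees in phase {phase}: {bad[:5]}")
        yes = int(ph["response"].sum())
        counts.append((yes, len(ph) - yes))
    (a, b), (c, d) = counts
    return ContingencyTable2x2(a, b, c, d)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    k: int
    genome_size: int
    table: ContingencyTable2x2
    chi2: float
    p: float
    expected_overlap: float

    @property
    def direction(self) -> str:
        if self.k > self.expected_overlap:
            return "enriched"
        if self.k < self.expected_overlap:
            return "depleted"
        return "as expected"


def _clean(genes: Iterable[str]) -> set[str]:
    cleaned = {g.strip() for g in genes}
    cleaned.discard("")
    return cleaned


def overlap_test(
    list_a: Iterable[str],
    list_b: Iterable[str],
    genome_size: int = HONEYBEE_GENOME_SIZE,
) -> OverlapResult:
    """Chi-square test of gene-list overlap against a genome background.

    Identifiers are whitespace-trimmed and deduplicated
    (case-sensitively); the 2x2 table partitions the genome into
    in-both / A-only / B-only / in-neither and is tested with the
    uncorrected Pearson chi-square.  The expected overlap under
    independence is ``|A| |B| / N``.
    """
    a = _clean(list_a)
    b = _clean(list_b)
    if not a or not b:
        raise ValueError("gene lists must be non-empty")
    if len(a | b) > genome_size:
        raise ValueError(
            f"union of lists ({len(a | b)}) exceeds genome size "
            f"{genome_size}")
    k = len(a & b)
    table = ContingencyTable2x2(
        k, len(a) - k, len(b) - k, genome_size - len(a) - len(b) + k)
    chi2, _, p = chi2_2x2(table)
    return OverlapResult(
        n_a=len(a), n_b=len(b), k=k, genome_size=genome_size,
        table=table, chi2=chi2, p=p,
        expected_overlap=len(a) * len(b) / genome_size,
    )


def overlap_test_from_counts(
    n_a: int, n_b: int, k: int, genome_size: int = HONEYBEE_GENOME_SIZE
) -> OverlapResult:
    """Overlap test from published list sizes and overlap count."""
    if k > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either list size")
    if n_a + n_b - k > genome_size:
        raise ValueError("union exceeds genome size")
    table = ContingencyTable2x2(k, n_a - k, n_b - k,
                                genome_size - n_a - n_b + k)
    chi2, _, p = chi2_2x2(table)
    return OverlapResult(
        n_a=n_a, n_b=n_b, k=k, genome_size=genome_size, table=table,
        chi2=chi2, p=p, expected_overlap=n_a * n_b / genome_size,
    )


def ddct_fold_change(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``ddCt = (Ct_target - Ct_reference)_test -
    (Ct_target - Ct_reference)_calibrator``; one extra cycle of ddCt
    halves the fold change.
    """
    cts = (ct_target_test, ct_reference_test,
           ct_target_calibrator, ct_reference_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_reference_test) - (
        ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
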