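"""Per-bee behavioral variables and the cumulative performance score.

Six unit-range variables are computed for each bee:

* Acq-1, Acq-2 — acquisition rate: conditioned responses to the CS+
  over conditioning trials 2-6 of phase 1 / phase 2, divided by 5.
  Trial 1 precedes any reinforcement and is never scored.
* DisCond-1, DisCond-2 — conditioning discrimination: CS+ responses on
  trials 2-6 that were *not* followed by a response to the next CS-
  presentation, divided by 5.
* DisT-1,-2 and DisT-3,-4 — retention discrimination: over the six
  same-concentration (CS+, CS-) probe pairs of a phase's two retention
  sets, pairs with a CS+ response and no CS- response, divided by 6.

The P-score is their unweighted sum (range 0-6); with denominators 5
and 6, thirty times any P-score is an integer.  The count of responses
to the eight oil/filter-paper control stimulations is kept alongside as
an arousal measure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .tables import ResponseTableError, validate_table

SCORE_COLUMNS = ["Acq1", "Acq2", "DisCond1", "DisCond2", "DisT12", "DisT34"]


def _check_binary6(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != (6,):
        raise ValueError(f"{name} must contain exactly 6 values, "
                         f"got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return arr


def acquisition_score(cs_plus_responses: Sequence[int]) -> float:
    """CS+ responses over conditioning trials 2-6, out of 5."""
    r = _check_binary6(cs_plus_responses, "cs_plus_responses")
    return float(r[1:].sum() / 5.0)


def discrimination_conditioning_score(
    cs_plus: Sequence[int], cs_minus: Sequence[int]
) -> float:
    """CS+ responses not followed by a CS- response, trials 2-6, out of 5.

    ``cs_minus[i]`` must be the response to the CS- presentation that
    immediately followed CS+ trial ``i`` in the alternating schedule.
    """
    p = _check_binary6(cs_plus, "cs_plus")
    m = _check_binary6(cs_minus, "cs_minus")
    return float(((p[1:] == 1) & (m[1:] == 0)).sum() / 5.0)


def discrimination_retention_score(
    paired_sets: Sequence[Sequence[tuple[int, int]]],
) -> float:
    """Clean (CS+ yes, CS- no) probe pairs over two retention sets, out of 6.

    ``paired_sets`` holds 2 sets of 3 same-concentration
    ``(cs_plus_response, cs_minus_response)`` pairs, in ascending
    concentration order.  Equivalently the mean of the two per-set
    scores each normalized to its 3 pairs.
    """
    if len(paired_sets) != 2 or any(len(s) != 3 for s in paired_sets):
        raise ValueError("expected 2 retention sets of 3 pairs each")
    count = 0
    for pairs in paired_sets:
        for plus, minus in pairs:
            if plus not in (0, 1) or minus not in (0, 1):
                raise ValueError("responses must be binary")
            count += int(plus == 1 and minus == 0)
    return count / 6.0


def _bee_arrays(rows: pd.DataFrame) -> dict:
    """Index one complete bee's responses by (phase, block, event_index)."""
    return {
        (p, b, i): int(r)
        for p, b, i, r in zip(rows["phase"], rows["block"],
                              rows["event_index"], rows["response"])
    }


def _conditioning_series(resp: dict, phase: int, role: str) -> list[int]:
    offset = 1 if role == "CSplus" else 2
    return [resp[(phase, "conditioning", offset + 2 * t)] for t in range(6)]


def _retention_pairs(resp: dict, phase: int) -> list[list[tuple[int, int]]]:
    sets = []
    for block in ("retention1", "retention2"):
        pairs = [
            (resp[(phase, block, 2 * c + 1)], resp[(phase, block, 2 * c + 2)])
            for c in range(3)
        ]
        sets.append(pairs)
    return sets


def control_response_count(bee_rows: pd.DataFrame) -> int:
    """Responses to the 8 oil/filter-paper controls (4 per phase)."""
    ctrl = bee_rows[bee_rows["stimulus_role"].isin(["oil", "paper"])]
    if len(ctrl) != 8:
        raise ValueError(
            f"expected 8 control events, found {len(ctrl)}; incomplete bee")
    return int(ctrl["response"].sum())


def score_bee(bee_rows: pd.DataFrame) -> dict:
    """Score one complete bee; returns the six variables plus totals."""
    resp = _bee_arrays(bee_rows)
    if len(resp) != 56 or len(bee_rows) != 56:
        raise ValueError("bee does not tile the 56-event protocol")
    acq1 = acquisition_score(_conditioning_series(resp, 1, "CSplus"))
    acq2 = acquisition_score(_conditioning_series(resp, 2, "CSplus"))
    dc1 = discrimination_conditioning_score(
        _conditioning_series(resp, 1, "CSplus"),
        _conditioning_series(resp, 1, "CSminus"))
    dc2 = discrimination_conditioning_score(
        _conditioning_series(resp, 2, "CSplus"),
        _conditioning_series(resp, 2, "CSminus"))
    dt12 = discrimination_retention_score(_retention_pairs(resp, 1))
    dt34 = discrimination_retention_score(_retention_pairs(resp, 2))
    return {
        "Acq1": acq1, "Acq2": acq2, "DisCond1": dc1, "DisCond2": dc2,
        "DisT12": dt12, "DisT34": dt34,
        "Pscore": acq1 + acq2 + dc1 + dc2 + dt12 + dt34,
        "control_responses": control_response_count(bee_rows),
    }


def score_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Score every bee of a validated response table.

    Returns one row per bee with the six variables, the P-score and the
    control-response count; deterministic and invariant to the row
    order of the input.
    """
    issues = validate_table(table)
    if issues:
        raise ResponseTableError(issues)
    records = []
    for bee_id, rows in table.groupby("bee_id", sort=True):
        rec = {
            "bee_id": bee_id,
            "colony": rows["colony"].iloc[0],
            "month": rows["month"].iloc[0],
            "group": int(rows["group"].iloc[0]),
        }
        rec.update(score_bee(rows))
        records.append(rec)
    return pd.DataFrame(records)
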