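"""Reading, writing and validating long-format per-bee response tables.

A response table has one row per (bee, stimulus event) with a binary
response column; a complete bee exactly tiles the 56-event protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .protocol import ProtocolSpec, build_protocol

#: required columns, in canonical order
COLUMNS = [
    "bee_id", "colony", "month", "group", "phase", "block",
    "event_index", "stimulus_role", "concentration", "response",
]

_KEY = ["bee_id", "phase", "block", "event_index"]


@dataclass(frozen=True)
class ValidationIssue:
    bee_id: str
    description: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.bee_id}: {self.description}"


class ResponseTableError(ValueError):
    """Raised when a response table fails structural validation."""

    def __init__(self, issues: list[ValidationIssue] | str):
        if isinstance(issues, str):
            super().__init__(issues)
            self.issues = []
        else:
            self.issues = issues
            lines = "\n".join(f"  - {i}" for i in issues[:20])
            more = "" if len(issues) <= 20 else f"\n  ... {len(issues) - 20} more"
            super().__init__(f"invalid response table:\n{lines}{more}")


def _delimiter_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a CSV/TSV response table.

    The delimiter is chosen from the extension (.tsv/.tab -> tab,
    anything else -> comma).  Raises :class:`ResponseTableError` when
    columns are missing, responses are not 0/1, or any bee does not
    exactly tile its group's protocol.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={
        "bee_id": str, "colony": str, "month": str,
    })
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"missing columns: {missing}")
    df = df[COLUMNS].copy()
    issues = validate_table(df)
    if issues:
        raise ResponseTableError(issues)
    return df


def write_response_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as CSV/TSV (delimiter from extension)."""
    table[COLUMNS].to_csv(path, sep=_delimiter_for(path), index=False)


def validate_table(
    table: pd.DataFrame, protocol: ProtocolSpec | None = None
) -> list[ValidationIssue]:
    """Check that every bee's rows exactly tile the protocol.

    Returns a list of issues (empty means valid); row order is
    irrelevant because events are matched by key.  When ``protocol`` is
    None each bee is checked against the protocol of its own ``group``
    value.
    """
    issues: list[ValidationIssue] = []
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        return [ValidationIssue("<table>", f"missing columns: {missing}")]

    bad_resp = ~table["response"].isin([0, 1])
    for pos in table.index[bad_resp]:
        row = table.loc[pos]
        issues.append(ValidationIssue(
            str(row["bee_id"]),
            f"non-binary response {row['response']!r} at "
            f"(phase={row['phase']}, block={row['block']}, "
            f"event_index={row['event_index']})",
        ))

    protocols = {g: build_protocol(g) for g in (1, 2)}
    expected_by_group = {
        g: {(e.phase, e.block, e.event_index): e for e in p}
        for g, p in protocols.items()
    }

    for bee_id, rows in table.groupby("bee_id", sort=False):
        groups = rows["group"].unique()
        if len(groups) != 1:
            issues.append(ValidationIssue(
                str(bee_id), f"inconsistent group labels {sorted(groups)}"))
            continue
        group = int(groups[0])
        if protocol is not None:
            expected = {(e.phase, e.block, e.event_index): e
                        for e in protocol}
        elif group in expected_by_group:
            expected = expected_by_group[group]
        else:
            issues.append(ValidationIssue(str(bee_id),
                                          f"unknown group {group}"))
            continue

        keys = list(zip(rows["phase"], rows["block"], rows["event_index"]))
        seen: set[tuple] = set()
        for key, (_, row) in zip(keys, rows.iterrows()):
            if key in seen:
                issues.append(ValidationIssue(
                    str(bee_id), f"duplicate event {key}"))
                continue
            seen.add(key)
            ev = expected.get(key)
            if ev is None:
                issues.append(ValidationIssue(
                    str(bee_id), f"unexpected event {key}"))
            elif (row["stimulus_role"] != ev.stimulus_role
                  or row["concentration"] != ev.concentration):
                issues.append(ValidationIssue(
                    str(bee_id),
                    f"event {key} labelled "
                    f"({row['stimulus_role']}, {row['concentration']}), "
                    f"protocol says ({ev.stimulus_role}, {ev.concentration})",
                ))
        absent = set(expected) - seen
        if absent:
            blocks = sorted({k[1] for k in absent})
            issues.append(ValidationIssue(
                str(bee_id),
                f"incomplete protocol: {len(absent)} events missing "
                f"from blocks {blocks}",
            ))
    return issues
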