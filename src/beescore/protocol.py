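"""Sequential olfactory PER conditioning protocol, expressed as data.

One run consists of two phases.  Each phase is one round of differential
conditioning (12 alternating trials, 6 CS+ and 6 CS-, starting with the
CS+, pure odors, CS+ reinforced with sucrose) followed by two sets of
retention tests.  A retention set presents the CS+ and CS- at ascending
concentrations (10^-3, 10^-2, pure), starting with the CS+, and ends with
one paraffin-oil and one plain filter-paper control stimulation.

Odor identities (PEA/OM in phase 1, OA/LA in phase 2, contingencies
swapped between the two bee groups) are carried as metadata only: scoring
is odor-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterator

BLOCKS = ("conditioning", "retention1", "retention2")
ROLES = ("CSplus", "CSminus", "oil", "paper")
CONCENTRATIONS = ("d3", "d2", "pure", "none")

#: numeric value of each odor concentration (fraction of pure odor)
CONCENTRATION_VALUE = {"d3": 1e-3, "d2": 1e-2, "pure": 1.0}

#: odor label per (group, phase, role); informational only
ODOR_ASSIGNMENT = {
    (1, 1, "CSplus"): "PEA", (1, 1, "CSminus"): "OM",
    (1, 2, "CSplus"): "OA", (1, 2, "CSminus"): "LA",
    (2, 1, "CSplus"): "OM", (2, 1, "CSminus"): "PEA",
    (2, 2, "CSplus"): "LA", (2, 2, "CSminus"): "OA",
}

#: pauses between protocol stages, in minutes; metadata only, never used
#: in any computation
TIMING_MINUTES = {
    "inter_trial_interval": 8,
    "conditioning_to_retention_pause": 20,
    "between_phase_pause": 30,
}


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus presentation within the protocol."""

    phase: int
    block: str
    event_index: int  # 1-based within block
    stimulus_role: str
    concentration: str
    reinforced: bool

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError(f"phase must be 1 or 2, got {self.phase}")
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.stimulus_role not in ROLES:
            raise ValueError(f"unknown stimulus_role {self.stimulus_role!r}")
        if self.concentration not in CONCENTRATIONS:
            raise ValueError(f"unknown concentration {self.concentration!r}")
        if self.event_index < 1:
            raise ValueError("event_index is 1-based")
        if self.reinforced and not (
            self.block == "conditioning" and self.stimulus_role == "CSplus"
        ):
            raise ValueError("only conditioning CS+ events are reinforced")
        control = self.stimulus_role in ("oil", "paper")
        if control != (self.concentration == "none"):
            raise ValueError("concentration 'none' iff control stimulus")
        if self.block == "conditioning" and self.concentration != "pure":
            raise ValueError("conditioning uses pure odors")

    @property
    def trial(self) -> int | None:
        """Conditioning trial number (1-6) for the event's own stimulus.

        The n-th CS+ (or CS-) conditioning event of a phase is "trial n";
        None outside the conditioning block.
        """
        if self.block != "conditioning":
            return None
        return (self.event_index + 1) // 2


@dataclass(frozen=True)
class ProtocolSpec:
    """The full ordered event sequence for one odor-contingency group."""

    group: int
    events: tuple[StimulusEvent, ...]

    def __iter__(self) -> Iterator[StimulusEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def odor(self, event: StimulusEvent) -> str | None:
        """Odor label presented for an event (None for controls)."""
        key = (self.group, event.phase, event.stimulus_role)
        return ODOR_ASSIGNMENT.get(key)

    def event_keys(self) -> set[tuple]:
        """(phase, block, event_index) keys; tiles a complete bee."""
        return {(e.phase, e.block, e.event_index) for e in self.events}

    def to_json(self, path=None) -> str:
        """Serialize the event list as JSON (one object per event)."""
        payload = {
            "group": self.group,
            "timing_minutes": TIMING_MINUTES,
            "events": [asdict(e) for e in self.events],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _retention_set(phase: int, block: str) -> list[StimulusEvent]:
    events = []
    idx = 1
    # ascending concentrations, CS+ first, CS- of the same concentration
    # immediately after (the pairing the retention discrimination score
    # consumes)
    for conc in ("d3", "d2", "pure"):
        for role in ("CSplus", "CSminus"):
            events.append(StimulusEvent(phase, block, idx, role, conc, False))
            idx += 1
    for role in ("oil", "paper"):
        events.append(StimulusEvent(phase, block, idx, role, "none", False))
        idx += 1
    return events


def build_protocol(group: int) -> ProtocolSpec:
    """Build the 56-event sequential-conditioning protocol for one group.

    Parameters
    ----------
    group
        Odor-contingency assignment, 1 or 2.  The group decides which
        odor is the CS+ in each phase; the event structure is identical.

    Returns
    -------
    ProtocolSpec
        Two phases x (12 alternating conditioning trials + 2 retention
        sets of 8 events each) = 56 events.
    """
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group!r}")
    events: list[StimulusEvent] = []
    for phase in (1, 2):
        for idx in range(1, 13):
            role = "CSplus" if idx % 2 == 1 else "CSminus"
            events.append(
                StimulusEvent(phase, "conditioning", idx, role, "pure",
                              reinforced=(role == "CSplus"))
            )
        events.extend(_retention_set(phase, "retention1"))
        events.extend(_retention_set(phase, "retention2"))
    return ProtocolSpec(group=group, events=tuple(events))
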