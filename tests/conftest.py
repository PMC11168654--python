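import numpy as np
import pandas as pd
import pytest

from beescore import CohortConfig, build_protocol, simulate_cohort
from beescore.tables import COLUMNS


def bee_table_from(protocol, respond, bee_id="bee_001", group=1):
    """Build a one-bee response table from a predicate over events."""
    rows = []
    for ev in protocol:
        rows.append({
            "bee_id": bee_id, "colony": "98", "month": "August",
            "group": group, "phase": ev.phase, "block": ev.block,
            "event_index": ev.event_index,
            "stimulus_role": ev.stimulus_role,
            "concentration": ev.concentration,
            "response": int(respond(ev)),
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def perfect_learner(ev):
    """CR to every CS+ from conditioning trial 2 on and every CS+ probe."""
    if ev.stimulus_role != "CSplus":
        return 0
    if ev.block == "conditioning":
        return int(ev.trial >= 2)
    return 1


@pytest.fixture(scope="session")
def protocol1():
    return build_protocol(1)


@pytest.fixture(scope="session")
def perfect_bee(protocol1):
    return bee_table_from(protocol1, perfect_learner)


@pytest.fixture(scope="session")
def zero_bee(protocol1):
    return bee_table_from(protocol1, lambda ev: 0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-bee simulated cohort reused across read-only tests."""
    table, traits = simulate_cohort(CohortConfig(n_bees=25, seed=42))
    return table, traits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
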