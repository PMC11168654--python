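"""Synthetic cohorts under an abrupt learner-state-switch model.

Group-average acquisition curves in PER conditioning rise gradually, but
individual bees do not: a bee performs at a low spontaneous rate until,
on some conditioning trial, it switches abruptly and permanently (within
a phase) into a learned state, after which it responds to the CS+ with a
high stable probability.  Gradual group curves emerge from heterogeneity
in switch times.  The simulator implements exactly that generative
story, per phase:

* naive state: every stimulus is answered at the bee's ``baseline``
  (spontaneous/arousal) rate;
* before each CS+ conditioning event from the 2nd onward, a naive bee
  switches to the learned state with probability ``switch_prob``;
* learned state: CS+ answered at ``asymptote`` (attenuated at retention
  dilutions by ``expit(sensitivity + log10(concentration))``, pure = 1),
  CS- answered at the phase's generalization probability, controls at
  ``baseline``.

Phase 2 uses a pair of structurally similar fatty-acid odors, so its
generalization probability is higher by default: discrimination is
harder in the second half of the procedure.  A latent "arousal" factor
is shared between sensitivity and baseline, and is correlated (by
``rho_traits``) with the latent behind switch_prob, so that fast
learners tend to be the more odor-sensitive, more spontaneously
responsive bees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log10

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .protocol import CONCENTRATION_VALUE, ProtocolSpec, build_protocol
from .tables import COLUMNS

_TRAIT_FIELDS = (
    "switch_prob", "asymptote", "generalization_p1",
    "generalization_p2", "sensitivity", "baseline",
)
_PROB_FIELDS = tuple(f for f in _TRAIT_FIELDS if f != "sensitivity")


@dataclass(frozen=True)
class BeeTraits:
    """Latent behavioral parameters of one simulated bee.

    All fields are probabilities in [0, 1] except ``sensitivity``, a
    real-valued log-concentration offset: a learned bee answers a CS+
    retention probe of concentration c with probability
    ``asymptote * expit(sensitivity + log10 c)``.
    """

    switch_prob: float
    asymptote: float
    generalization_p1: float
    generalization_p2: float
    sensitivity: float
    baseline: float

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TraitComponent:
    """One mixture component of the cohort's trait distribution.

    ``means`` are the central values of each trait; ``sd`` are the
    dispersions of the latent normals (logit scale for probability
    traits, raw scale for sensitivity).  Zero dispersion collapses the
    component onto its means.
    """

    weight: float
    means: BeeTraits
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")
        for name, v in self.sd.items():
            if name not in _TRAIT_FIELDS:
                raise ValueError(f"unknown trait {name!r}")
            if v < 0:
                raise ValueError(f"negative dispersion for {name!r}")


# Defaults emulate the study cohort: 171 bees, roughly 0.69/0.31 split
# into a fast-learning and a slow-learning component (soft-calibrated so
# the components' mean Acq-1 land near 0.76 and 0.13), phase-2
# generalization well above phase-1, and sensitivity/arousal coupled to
# learning speed.
_HIGH = TraitComponent(
    weight=0.69,
    means=BeeTraits(switch_prob=0.52, asymptote=0.93,
                    generalization_p1=0.08, generalization_p2=0.45,
                    sensitivity=3.5, baseline=0.12),
    sd={"switch_prob": 0.6, "asymptote": 0.5, "generalization_p1": 0.5,
        "generalization_p2": 0.5, "sensitivity": 1.0, "baseline": 0.5},
)
_LOW = TraitComponent(
    weight=0.31,
    means=BeeTraits(switch_prob=0.05, asymptote=0.5,
                    generalization_p1=0.10, generalization_p2=0.35,
                    sensitivity=0.5, baseline=0.05),
    sd={"switch_prob": 0.6, "asymptote": 0.5, "generalization_p1": 0.5,
        "generalization_p2": 0.5, "sensitivity": 1.0, "baseline": 0.5},
)

def separated_components() -> tuple[TraitComponent, TraitComponent]:
    """Two well-separated trait components for recovery checks.

    Calibrated so the resulting P-score mixture components sit near
    means 4.5 and 1.0 with SDs around 0.6 — far enough apart that the
    2.6 performer threshold should recover true mixture membership.
    """
    sd = {"switch_prob": 0.4, "asymptote": 0.4, "generalization_p1": 0.4,
          "generalization_p2": 0.4, "sensitivity": 0.6, "baseline": 0.4}
    fast = TraitComponent(
        weight=0.5,
        means=BeeTraits(switch_prob=0.6, asymptote=0.93,
                        generalization_p1=0.05, generalization_p2=0.2,
                        sensitivity=3.5, baseline=0.1),
        sd=sd,
    )
    slow = TraitComponent(
        weight=0.5,
        means=BeeTraits(switch_prob=0.05, asymptote=0.5,
                        generalization_p1=0.05, generalization_p2=0.1,
                        sensitivity=-0.5, baseline=0.08),
        sd=sd,
    )
    return fast, slow


_COLONIES = ("67", "73", "98", "299")
_MONTHS = ("July", "August", "September", "October")


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible specification of a simulated cohort."""

    n_bees: int = 171
    seed: int = 0
    rho_traits: float = 0.7
    group_split: float = 0.5
    components: tuple[TraitComponent, ...] = (_HIGH, _LOW)

    def __post_init__(self) -> None:
        if self.n_bees < 1:
            raise ValueError("n_bees must be >= 1")
        if not -1.0 <= self.rho_traits <= 1.0:
            raise ValueError("rho_traits must lie in [-1, 1]")
        if not self.components:
            raise ValueError("at least one trait component is required")
        if sum(c.weight for c in self.components) <= 0:
            raise ValueError("component weights must sum to > 0")


def _clip_logit(p: float) -> float:
    return float(logit(min(max(p, 1e-12), 1.0 - 1e-12)))


def _trait_rng(config: CohortConfig, bee_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, bee_index, 0]))


def _response_rng(config: CohortConfig, bee_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, bee_index, 1]))


def draw_traits(
    config: CohortConfig, bee_index: int
) -> tuple[BeeTraits, int]:
    """Draw one bee's traits; deterministic given (seed, bee_index).

    Returns ``(traits, component_index)`` so parameter-recovery tests
    can compare inferred against true mixture membership.

    Probability traits are logit-normal around the component means.
    Two correlated latent standard normals drive the draw: one behind
    ``switch_prob``, one ("arousal") shared by ``sensitivity`` and
    ``baseline``; their correlation is ``rho_traits``.  The two
    generalization traits share a third latent, which keeps
    ``generalization_p2 >= generalization_p1`` whenever the component
    means are ordered that way with equal dispersions.
    """
    rng = _trait_rng(config, bee_index)
    weights = np.array([c.weight for c in config.components], float)
    comp_idx = int(rng.choice(len(weights), p=weights / weights.sum()))
    comp = config.components[comp_idx]

    rho = config.rho_traits
    z_switch = rng.standard_normal()
    z_arousal = rho * z_switch + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
    z_gen = rng.standard_normal()
    z_asym = rng.standard_normal()
    latents = {
        "switch_prob": z_switch, "sensitivity": z_arousal,
        "baseline": z_arousal, "generalization_p1": z_gen,
        "generalization_p2": z_gen, "asymptote": z_asym,
    }

    values = {}
    for name in _TRAIT_FIELDS:
        mean = getattr(comp.means, name)
        sd = comp.sd.get(name, 0.0)
        if sd == 0.0:
            values[name] = mean
        elif name == "sensitivity":
            values[name] = mean + sd * latents[name]
        else:
            values[name] = float(expit(_clip_logit(mean) + sd * latents[name]))
    return BeeTraits(**values), comp_idx


def simulate_bee(
    traits: BeeTraits,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one bee's binary responses to every protocol event.

    The returned array is aligned with ``protocol.events``.  The first
    conditioning trial is generated like any other naive-state event
    (scoring later discards it); learned state resets between phases.
    """
    probs = np.empty(len(protocol.events))
    learned = {1: False, 2: False}
    for i, ev in enumerate(protocol.events):
        if (ev.block == "conditioning" and ev.stimulus_role == "CSplus"
                and ev.trial >= 2 and not learned[ev.phase]):
            if rng.random() < traits.switch_prob:
                learned[ev.phase] = True
        if not learned[ev.phase] or ev.stimulus_role in ("oil", "paper"):
            probs[i] = traits.baseline
        elif ev.stimulus_role == "CSplus":
            if ev.block == "conditioning":
                probs[i] = traits.asymptote
            else:
                c = CONCENTRATION_VALUE[ev.concentration]
                probs[i] = traits.asymptote * expit(
                    traits.sensitivity + log10(c))
        else:  # CS- for a learned bee: phase-specific generalization
            probs[i] = (traits.generalization_p1 if ev.phase == 1
                        else traits.generalization_p2)
    return (rng.random(len(probs)) < probs).astype(int)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; fully reproducible from ``config.seed``.

    Returns ``(response_table, trait_table)``.  The response table has
    one row per (bee, event) in the standard long format; the trait
    table records each bee's true traits and mixture component for
    parameter-recovery checks.
    """
    protocols = {1: build_protocol(1), 2: build_protocol(2)}
    n_group1 = round(config.n_bees * config.group_split)
    width = max(3, len(str(config.n_bees)))

    rows: list[dict] = []
    trait_rows: list[dict] = []
    for bee_index in range(config.n_bees):
        bee_id = f"bee_{bee_index + 1:0{width}d}"
        group = 1 if bee_index < n_group1 else 2
        colony = _COLONIES[bee_index % len(_COLONIES)]
        month = _MONTHS[(bee_index // len(_COLONIES)) % len(_MONTHS)]
        traits, comp_idx = draw_traits(config, bee_index)
        protocol = protocols[group]
        responses = simulate_bee(
            traits, protocol, _response_rng(config, bee_index))
        for ev, r in zip(protocol.events, responses):
            rows.append({
                "bee_id": bee_id, "colony": colony, "month": month,
                "group": group, "phase": ev.phase, "block": ev.block,
                "event_index": ev.event_index,
                "stimulus_role": ev.stimulus_role,
                "concentration": ev.concentration, "response": int(r),
            })
        trait_rows.append({"bee_id": bee_id, "group": group,
                           "component": comp_idx, **asdict(traits)})
    table = pd.DataFrame(rows, columns=COLUMNS)
    traits_df = pd.DataFrame(trait_rows)
    return table, traits_df
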