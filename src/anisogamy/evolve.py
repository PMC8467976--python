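"""Stochastic trait-substitution evolution.

Mutations arise one at a time (separated timescales: each invasion completes
before the next mutation appears), at a fixed rate per adult, so the mutating
class is drawn with probability proportional to its adult count.  A size
mutation moves the gamete size by exactly +/- delta_m with equal probability;
proposals that would fall below the minimum viable gamete size are discarded
and redrawn.  Optionally, a proposal is instead a switch to obligate
asexuality with a small probability (mutations to asexuality are rarer than
size mutations).  Each proposal is resolved by deterministic invasion
dynamics; on fixation the ancestor is replaced and the population
re-equilibrated.  The walk ends when ``stop_k`` consecutive proposals fail to
invade (the evolutionarily stable state "from which it cannot leave").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AdultClass,
    MatingType,
    ModelParams,
    NotAtEquilibriumError,
    PopulationState,
    ReproductiveMode,
)
from .generation import iterate_to_equilibrium
from .invasion import Verdict, invade_asexual, invade_size_mutant

__all__ = [
    "EventType",
    "EvolutionRecord",
    "EvolutionTrajectory",
    "propose_mutation",
    "run_adaptive_walk",
]


class EventType(str, enum.Enum):
    SIZE_FIXED = "SIZE_FIXED"
    SIZE_LOST = "SIZE_LOST"
    ASEX_FIXED = "ASEX_FIXED"
    ASEX_LOST = "ASEX_LOST"
    MACRO_EXTINCT = "MACRO_EXTINCT"
    ESS_REACHED = "ESS_REACHED"


@dataclass(frozen=True)
class EvolutionRecord:
    substitution_index: int
    mx: float | None  # gamete size of the extant X-type class (None if extinct)
    my: float | None
    R: float
    event: EventType


@dataclass
class EvolutionTrajectory:
    records: list[EvolutionRecord]
    final_state: PopulationState
    seed: int
    truncated: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.substitution_index, r.mx, r.my, r.R, r.event.value)
                for r in self.records
            ],
            columns=["substitution_index", "mx", "my", "R", "event"],
        )

    def events(self) -> list[EventType]:
        return [r.event for r in self.records]


def propose_mutation(
    state: PopulationState, rng: np.random.Generator
) -> tuple[AdultClass, float]:
    """Draw (target class, signed size step) for the next mutation.

    The target is sampled proportionally to adult counts; the step is
    ``+/- delta_m`` with probability 1/2 each.  Inviable proposals (below the
    minimum gamete size) are discarded and redrawn.
    """
    params = state.params
    extant = state.extant
    if not extant:
        raise ValueError("no extant classes to mutate")
    weights = np.array([c.count for c in extant], float)
    weights /= weights.sum()
    while True:
        target = extant[rng.choice(len(extant), p=weights)]
        delta = params.delta_m if rng.random() < 0.5 else -params.delta_m
        if target.m + delta >= params.m_min - 1e-9 * params.m_min:
            return target, delta


def _trait_sizes(state: PopulationState) -> tuple[float | None, float | None]:
    mx = my = None
    for c in state.extant:
        if c.mating_type is MatingType.X:
            mx = c.m if mx is None else max(mx, c.m)
        else:
            my = c.m if my is None else max(my, c.m)
    return mx, my


def _sexual_types(state: PopulationState) -> set[MatingType]:
    return {c.mating_type for c in state.extant if c.is_sexual}


def _prune(state: PopulationState) -> PopulationState:
    state.classes = [c for c in state.classes if c.count > 0]
    return state


def run_adaptive_walk(
    initial: PopulationState,
    params: ModelParams | None = None,
    include_asexual_mutations: bool = False,
    asex_rate_ratio: float = 0.05,
    stop_k: int = 50,
    rng: np.random.Generator | int | None = None,
    max_substitutions: int = 10_000,
    equilibrium_tol: float = 1e-10,
    equilibrate_initial: bool = True,
) -> EvolutionTrajectory:
    """Run one stochastic trait-substitution walk to an evolutionarily
    stable state.

    With ``equilibrate_initial`` (default) the starting population is first
    iterated to demographic equilibrium; otherwise a drifting start raises
    :class:`NotAtEquilibriumError`.  When ``include_asexual_mutations`` is on,
    each proposal is a switch to obligate asexuality with probability
    ``asex_rate_ratio`` and the walk keeps evolving progeny size after an
    asexual takeover until that lineage reaches its own optimum.  The walk is
    fully reproducible: same seed and parameters give an identical record
    sequence.
    """
    if params is None:
        params = initial.params
    seed = params.rng_seed
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    state = initial.copy()
    if equilibrate_initial:
        state = _prune(iterate_to_equilibrium(state, tol=1e-13).state)
    else:
        from .invasion import assert_at_equilibrium

        assert_at_equilibrium(state, equilibrium_tol)

    records: list[EvolutionRecord] = []
    failures = 0
    truncated = False

    def snapshot(index: int, event: EventType) -> None:
        mx, my = _trait_sizes(state)
        records.append(EvolutionRecord(index, mx, my, state.asr(), event))

    index = 0
    while failures < stop_k:
        index += 1
        if index > max_substitutions:
            truncated = True
            break
        is_asex = (
            include_asexual_mutations
            and any(c.is_sexual for c in state.extant)
            and rng.random() < asex_rate_ratio
        )
        sexual_before = _sexual_types(state)
        if is_asex:
            weights = np.array([c.count for c in state.extant], float)
            weights /= weights.sum()
            target = state.extant[rng.choice(len(state.extant), p=weights)]
            outcome = invade_asexual(
                state, target.mating_type, check_equilibrium=False
            )
            fixed = outcome.verdict is Verdict.MUTANT_FIXED
            event = EventType.ASEX_FIXED if fixed else EventType.ASEX_LOST
        else:
            target, delta = propose_mutation(state, rng)
            outcome = invade_size_mutant(
                state, target.mating_type, delta, check_equilibrium=False
            )
            fixed = outcome.verdict in (
                Verdict.MUTANT_FIXED,
                Verdict.MACROGAMETE_EXTINCT_DE_FACTO_ASEXUAL,
            )
            event = EventType.SIZE_FIXED if fixed else EventType.SIZE_LOST

        if fixed:
            failures = 0
            state = _prune(iterate_to_equilibrium(outcome.final_state, tol=1e-13).state)
            if len(sexual_before) == 2 and len(_sexual_types(state)) == 1:
                snapshot(index, EventType.MACRO_EXTINCT)
            snapshot(index, event)
        else:
            failures += 1
            snapshot(index, event)

    snapshot(index, EventType.ESS_REACHED)
    return EvolutionTrajectory(records, state, seed, truncated=truncated)
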