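"""Invasion analysis: introduce one mutant class and classify its fate.

A mutation arises in one resident adult: the ancestor class loses one adult
and a new mutant class of count 1 appears (total adult number unchanged), and
the deterministic generation map is iterated.
Because dynamics are expected-value recursions with an extinction threshold,
invasions resolve dichotomously: the mutant class either falls below the
threshold (lost) or displaces every same-mating-type resident class (fixed).
A third outcome is possible when parthenogenesis skews the adult sex ratio so
far that the opposite mating type is culled: the population becomes de facto
asexual (no partners left to fuse with), which is reported as its own verdict.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

from .core import (
    AdultClass,
    InvalidParameterError,
    InvalidStrategyError,
    MatingType,
    NotAtEquilibriumError,
    PopulationState,
    ReproductiveMode,
)
from .generation import Structure, _rebuild

__all__ = ["Verdict", "InvasionOutcome", "invade_size_mutant", "invade_asexual",
           "assert_at_equilibrium"]

_mutant_counter = itertools.count()


class Verdict(str, enum.Enum):
    MUTANT_FIXED = "MUTANT_FIXED"
    MUTANT_LOST = "MUTANT_LOST"
    MACROGAMETE_EXTINCT_DE_FACTO_ASEXUAL = "MACROGAMETE_EXTINCT_DE_FACTO_ASEXUAL"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class InvasionOutcome:
    verdict: Verdict
    final_state: PopulationState
    generations_elapsed: int


def assert_at_equilibrium(state: PopulationState, tol: float = 1e-6) -> None:
    """Probe one generation and require class frequencies to be stationary."""
    struct = Structure(state)
    counts = [c.count for c in state.classes]
    after = struct.advance(list(counts))
    A = state.params.A
    drift = max(abs(a - b) / A for a, b in zip(after, counts))
    if drift > tol:
        raise NotAtEquilibriumError(
            f"resident frequencies drift by {drift:.3e} per generation (tol {tol:.1e})"
        )


def _ancestor(
    state: PopulationState, mating_type: MatingType, sexual_only: bool = False
) -> AdultClass:
    """The extant resident class of the given mating type.

    If several coexist, the most abundant one is treated as the ancestor.
    """
    candidates = [
        c
        for c in state.extant
        if c.mating_type is mating_type and (c.is_sexual or not sexual_only)
    ]
    if not candidates:
        raise InvalidParameterError(
            f"no extant resident of mating type {mating_type.value}"
        )
    return max(candidates, key=lambda c: c.count)


def _snap(value: float, delta_m: float) -> float:
    """Snap a trait value to the mutational lattice when within rounding
    error of it, so repeated +/- delta_m steps never accumulate drift."""
    snapped = round(value / delta_m) * delta_m
    if abs(snapped - value) < 1e-9 * max(1.0, abs(value)):
        return snapped
    return value


def _run(
    invaded: PopulationState,
    mutant_id: str,
    displaced_ids: list[str],
    watch_opposite: bool,
) -> InvasionOutcome:
    """Iterate until the mutant or its competitors are culled.

    ``displaced_ids`` are the resident classes the mutant must outcompete for
    fixation.  With ``watch_opposite``, loss of the mutant's opposite sexual
    mating type stops the run with the de facto asexual verdict.
    """
    params = invaded.params
    struct = Structure(invaded)
    counts = [c.count for c in invaded.classes]
    idx = {cid: i for i, cid in enumerate(struct.ids)}
    i_mut = idx[mutant_id]
    mut_type = struct.mating_type[i_mut]
    displaced = [idx[cid] for cid in displaced_ids]
    opposite = [
        i
        for i in range(struct.n)
        if struct.sexual[i] and struct.mating_type[i] is not mut_type
    ]
    watch_opposite = watch_opposite and bool(opposite)

    gens = 0
    verdict = Verdict.UNRESOLVED
    for gens in range(1, params.max_generations + 1):
        counts = struct.advance(counts)
        if counts[i_mut] <= 0.0:
            verdict = Verdict.MUTANT_LOST
            break
        if watch_opposite and all(counts[i] <= 0.0 for i in opposite):
            verdict = Verdict.MACROGAMETE_EXTINCT_DE_FACTO_ASEXUAL
            break
        if all(counts[i] <= 0.0 for i in displaced):
            verdict = Verdict.MUTANT_FIXED
            break
    final = _rebuild(invaded, counts, invaded.generation_index + gens)
    return InvasionOutcome(verdict, final, gens)


def invade_size_mutant(
    resident: PopulationState,
    target_type: MatingType,
    delta: float,
    equilibrium_tol: float = 1e-6,
    check_equilibrium: bool = True,
) -> InvasionOutcome:
    """Introduce one adult producing gametes of size ``ancestor.m + delta``.

    The mutant keeps its ancestor's mating type and (sexual) mode.  Mutations
    taking the size below the minimum viable gamete size are inviable and are
    rejected outright.
    """
    params = resident.params
    if check_equilibrium:
        assert_at_equilibrium(resident, equilibrium_tol)
    anc = _ancestor(resident, MatingType(target_type))
    new_m = _snap(anc.m + delta, params.delta_m)
    if new_m < params.m_min - 1e-9 * params.m_min:
        raise InvalidStrategyError(
            f"mutant gamete size {new_m:.6g} below minimum viable size {params.m_min:.6g}"
        )
    invaded = resident.copy()
    invaded.by_id(anc.class_id).count = max(anc.count - 1.0, 0.0)
    mutant_id = f"{anc.class_id}^{next(_mutant_counter)}"
    invaded.classes.append(
        AdultClass(mutant_id, anc.mating_type, anc.mode, max(new_m, params.m_min), 1.0)
    )
    displaced = [
        c.class_id
        for c in resident.extant
        if c.mating_type is anc.mating_type and c.mode is anc.mode
    ]
    return _run(invaded, mutant_id, displaced, watch_opposite=anc.is_sexual)


def invade_asexual(
    resident: PopulationState,
    ancestor_type: MatingType,
    equilibrium_tol: float = 1e-6,
    check_equilibrium: bool = True,
) -> InvasionOutcome:
    """Introduce one obligately asexual adult inheriting its ancestor's size.

    The mutant never takes part in fertilisation; all its gametes attempt the
    parthenogenetic route.  Fixation means both resident sexual classes are
    displaced.
    """
    if check_equilibrium:
        assert_at_equilibrium(resident, equilibrium_tol)
    anc = _ancestor(resident, MatingType(ancestor_type), sexual_only=True)
    invaded = resident.copy()
    invaded.by_id(anc.class_id).count = max(anc.count - 1.0, 0.0)
    mutant_id = f"{anc.class_id}a{next(_mutant_counter)}"
    invaded.classes.append(
        AdultClass(
            mutant_id, anc.mating_type, ReproductiveMode.OBLIGATE_ASEXUAL, anc.m, 1.0
        )
    )
    displaced = [c.class_id for c in resident.extant if c.is_sexual]
    return _run(invaded, mutant_id, displaced, watch_opposite=False)
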