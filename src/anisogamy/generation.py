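"""One full generation of the life cycle, and iteration to equilibrium.

The per-generation map is: gametogenesis (each adult converts its budget M
into M/m gametes) → mass-action fertilisation → survival (Vance functions for
zygotes and parthenosporophytes) → meiotic splitting (each surviving zygote
yields exactly two haploid adults, one inheriting each parental class; this
deterministic half/half split is the expected value of Mendelian mating-type
inheritance and is the convention that reproduces the closed-form adult sex
ratio) → density regulation (pure rescaling of all counts so the total is A)
→ extinction culling (classes below the extinction threshold are zeroed and
the remainder re-normalised to A).

Dynamics are deterministic expected-value recursions; finiteness of the adult
population enters only through the extinction threshold.  The inner kernel
(`Structure.advance`) is deliberately plain-float Python with all survival
factors precomputed: class sizes are fixed within an invasion, only counts
change, and trait-substitution walks need ~1e5 of these updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    INFINITE,
    InvalidParameterError,
    MatingType,
    ModelParams,
    PopulationCollapseError,
    PopulationState,
    ReproductiveMode,
    parthenosporophyte_survival,
    zygote_survival,
)
from .kinetics import remaining_after_kinetics

__all__ = ["step", "iterate_to_equilibrium", "EquilibriumResult", "Structure"]


class Structure:
    """Frozen class structure (sizes, types, modes) with precomputed factors.

    ``advance(counts)`` maps adult counts through one generation.  Build once
    per invasion; reuse across generations.
    """

    __slots__ = (
        "n",
        "ids",
        "m",
        "mating_type",
        "sexual",
        "x_idx",
        "y_idx",
        "per_adult",
        "sp",
        "sz",
        "phi",
        "A",
        "threshold",
        "inv_AM",
    )

    def __init__(self, state: PopulationState):
        p = state.params
        self.n = len(state.classes)
        self.ids = [c.class_id for c in state.classes]
        self.m = [c.m for c in state.classes]
        self.mating_type = [c.mating_type for c in state.classes]
        self.sexual = [c.is_sexual for c in state.classes]
        self.x_idx = [
            i
            for i in range(self.n)
            if self.sexual[i] and self.mating_type[i] is MatingType.X
        ]
        self.y_idx = [
            i
            for i in range(self.n)
            if self.sexual[i] and self.mating_type[i] is MatingType.Y
        ]
        self.per_adult = [p.M / c.m for c in state.classes]
        self.sp = [parthenosporophyte_survival(p.beta_p, c.m) for c in state.classes]
        # zygote survival for every compatible (x, y) class pair
        self.sz = [
            [zygote_survival(p.beta_z, self.m[i], self.m[j]) for j in self.y_idx]
            for i in self.x_idx
        ]
        self.phi = p.phi
        self.A = p.A
        self.threshold = p.extinction_threshold
        self.inv_AM = 1.0 / (p.A * p.M)

    def advance(self, counts: list[float]) -> list[float]:
        """One generation; returns post-regulation, post-culling counts."""
        gametes = [counts[i] * self.per_adult[i] for i in range(self.n)]
        NX = sum(gametes[i] for i in self.x_idx)
        NY = sum(gametes[j] for j in self.y_idx)

        if NX > 0.0 and NY > 0.0 and self.phi > 0.0:
            if math.isinf(self.phi):
                fused = min(NX, NY)
            else:
                # kinetics run on densities (gametes per unit population mass)
                nx, _ = remaining_after_kinetics(
                    NX * self.inv_AM, NY * self.inv_AM, self.phi
                )
                fused = NX - nx / self.inv_AM
        else:
            fused = 0.0

        new = [0.0] * self.n
        if fused > 0.0:
            wx = [gametes[i] / NX for i in self.x_idx]
            wy = [gametes[j] / NY for j in self.y_idx]
            # each surviving zygote of pair (i, j) adds one adult to i and one to j
            for a, i in enumerate(self.x_idx):
                row = self.sz[a]
                mean_sz = 0.0
                for b in range(len(self.y_idx)):
                    mean_sz += wy[b] * row[b]
                new[i] += fused * wx[a] * mean_sz
            for b, j in enumerate(self.y_idx):
                col_mean = 0.0
                for a in range(len(self.x_idx)):
                    col_mean += wx[a] * self.sz[a][b]
                new[j] += fused * wy[b] * col_mean
            frac_x = fused / NX
            frac_y = fused / NY
        else:
            frac_x = frac_y = 0.0

        for i in range(self.n):
            left = gametes[i]
            if self.sexual[i]:
                left *= (1.0 - frac_x) if self.mating_type[i] is MatingType.X else (
                    1.0 - frac_y
                )
            new[i] += left * self.sp[i]

        total = sum(new)
        if total <= 0.0:
            raise PopulationCollapseError(
                "no adults survived; population collapsed"
            )
        scale = self.A / total
        new = [c * scale for c in new]
        if self.threshold > 0.0:
            culled = False
            for i in range(self.n):
                if 0.0 < new[i] < self.threshold:
                    new[i] = 0.0
                    culled = True
            if culled:
                total = sum(new)
                if total <= 0.0:
                    raise PopulationCollapseError(
                        "every class fell below the extinction threshold"
                    )
                scale = self.A / total
                new = [c * scale for c in new]
        return new


def _rebuild(state: PopulationState, counts: list[float], gen: int) -> PopulationState:
    out = state.copy()
    for c, n in zip(out.classes, counts):
        c.count = n
    out.generation_index = gen
    return out


def step(state: PopulationState) -> PopulationState:
    """Advance the population by one full generation."""
    if not any(c.count > 0 for c in state.classes):
        raise InvalidParameterError("step requires at least one class with count > 0")
    struct = Structure(state)
    counts = struct.advance([c.count for c in state.classes])
    return _rebuild(state, counts, state.generation_index + 1)


@dataclass
class EquilibriumResult:
    state: PopulationState
    converged: bool
    generations: int
    oscillating: bool = False


def iterate_to_equilibrium(
    state: PopulationState,
    tol: float = 1e-12,
    max_gen: int | None = None,
) -> EquilibriumResult:
    """Iterate the generation map with fixed strategies until class
    frequencies stop changing (max absolute change < ``tol``).

    Detects period-2 cycles (frequencies returning after two steps while
    still moving between consecutive steps) and reports them as
    non-convergent rather than looping to ``max_gen``.
    """
    if max_gen is None:
        max_gen = state.params.max_generations
    struct = Structure(state)
    counts = [c.count for c in state.classes]
    A = state.params.A
    prev = [c / A for c in counts] if A else counts
    prev2: list[float] | None = None
    gens = 0
    for gens in range(1, max_gen + 1):
        counts = struct.advance(counts)
        freqs = [c / A for c in counts]
        delta = max(abs(f - g) for f, g in zip(freqs, prev))
        if delta < tol:
            return EquilibriumResult(
                _rebuild(state, counts, state.generation_index + gens), True, gens
            )
        if prev2 is not None:
            cycle = max(abs(f - g) for f, g in zip(freqs, prev2))
            if cycle < tol:
                return EquilibriumResult(
                    _rebuild(state, counts, state.generation_index + gens),
                    False,
                    gens,
                    oscillating=True,
                )
        prev2, prev = prev, freqs
    return EquilibriumResult(
        _rebuild(state, counts, state.generation_index + gens), False, gens
    )
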