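"""Mass-action fertilisation kinetics over the fertilisation window.

Gametes of opposite mating type fuse at a size-independent rate; the joint
effect of encounter rate and window length is the single dimensionless
parameter ``phi``.  Aggregate dynamics over dimensionless time are

    dnx/dt = dny/dt = -nx * ny,

whose closed form (with D = ny0 - nx0 conserved) is

    nx(phi) = nx0 / (nx0 * expm1(D*phi)/D + exp(D*phi)),

smooth through D = 0 where it reduces to ``n0 / (1 + n0*phi)``.  In the
``phi = INFINITE`` (gamete-competition) limit the scarcer side fuses
completely and only the majority side leaves unfused gametes.

Densities here are gametes per unit total population mass: a class with adult
frequency ``f`` and gamete size ``m`` enters at density ``f/m``.  This
normalisation makes finite-phi outcomes independent of the absolute adult
number ``A`` and budget ``M``; it is this package's declared convention (any
other normalisation rescales ``phi`` and hence changes quantitative finite-phi
outcomes, while every ``phi = INFINITE`` result is unaffected).  Obligately
asexual classes appear in the pool at full density but never participate in
fusion; every gamete they produce takes the parthenogenetic route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import (
    INFINITE,
    InvalidParameterError,
    MatingType,
    PopulationState,
    UndefinedFractionError,
)

__all__ = [
    "GametePool",
    "FertilizationResult",
    "run_kinetics",
    "fertilized_fraction_rare_mutant",
    "remaining_after_kinetics",
]


@dataclass
class GametePool:
    """Per-class gamete densities entering the fertilisation window."""

    density: dict[str, float]
    side: dict[str, MatingType]
    participating: dict[str, bool]

    def __post_init__(self) -> None:
        for cid, d in self.density.items():
            if d < 0:
                raise InvalidParameterError(f"negative gamete density for {cid!r}: {d}")

    @classmethod
    def from_state(cls, state: PopulationState) -> "GametePool":
        total = state.total
        density, side, part = {}, {}, {}
        for c in state.classes:
            freq = c.count / total if total > 0 else 0.0
            density[c.class_id] = freq / c.m
            side[c.class_id] = c.mating_type
            part[c.class_id] = c.is_sexual
        return cls(density, side, part)

    def side_total(self, mating_type: MatingType) -> float:
        return sum(
            d
            for cid, d in self.density.items()
            if self.participating[cid] and self.side[cid] is mating_type
        )


@dataclass
class FertilizationResult:
    """Outcome of one fertilisation window.

    ``zygotes`` maps (x_class_id, y_class_id) pairs to zygote densities;
    ``leftover`` holds the unfused density of every class (asexual classes
    keep their full input); ``fertilized_fraction`` is the per-class
    probability that one of its gametes fused.
    """

    zygotes: dict[tuple[str, str], float]
    leftover: dict[str, float]
    fertilized_fraction: dict[str, float]

    def total_zygotes(self) -> float:
        return sum(self.zygotes.values())

    def to_jsonable(self) -> dict:
        return {
            "zygotes": {f"{x}|{y}": v for (x, y), v in self.zygotes.items()},
            "leftover": dict(self.leftover),
            "fertilized_fraction": dict(self.fertilized_fraction),
        }


def remaining_after_kinetics(nx0: float, ny0: float, phi: float) -> tuple[float, float]:
    """Aggregate unfused densities (nx, ny) after dimensionless time ``phi``.

    Closed form of the two-species annihilation ODE; handles ``phi=INFINITE``
    (minority side fully consumed) and the symmetric case smoothly.
    """
    if nx0 < 0 or ny0 < 0:
        raise InvalidParameterError("gamete densities must be non-negative")
    if nx0 == 0.0 or ny0 == 0.0 or phi == 0.0:
        return nx0, ny0
    if math.isinf(phi):
        fused = min(nx0, ny0)
        return nx0 - fused, ny0 - fused
    # evaluate on the minority side (no cancellation as it is exhausted);
    # the majority side follows exactly from the conserved difference
    if nx0 <= ny0:
        minority0, d = nx0, ny0 - nx0
    else:
        minority0, d = ny0, nx0 - ny0
    dphi = d * phi
    if dphi > 700.0:  # e^{d*phi} overflows; minority side fully exhausted
        minority = 0.0
    else:
        growth = math.exp(dphi)
        ratio = phi if d == 0.0 else math.expm1(dphi) / d
        minority = minority0 / (minority0 * ratio + growth)
    if nx0 <= ny0:
        return minority, minority + d
    return minority + d, minority


def run_kinetics(pool: GametePool, phi: float) -> FertilizationResult:
    """Pair compatible gamete classes by mass action for a window ``phi``.

    Within each mating-type side, classes decay proportionally (the encounter
    rate is size independent), so fusions are apportioned by initial
    within-side shares and the zygote density of a pair is the product of the
    two sides' shares times the total number of fusions.
    """
    if not (phi >= 0):
        raise InvalidParameterError(f"phi must be >= 0 or INFINITE, got {phi!r}")
    x_ids = [
        cid
        for cid, s in pool.side.items()
        if s is MatingType.X and pool.participating[cid]
    ]
    y_ids = [
        cid
        for cid, s in pool.side.items()
        if s is MatingType.Y and pool.participating[cid]
    ]
    nx0 = sum(pool.density[c] for c in x_ids)
    ny0 = sum(pool.density[c] for c in y_ids)

    nx, ny = remaining_after_kinetics(nx0, ny0, phi)
    # difference taken on the minority side, which is the one exhausted
    fused = min(nx0, ny0) - min(nx, ny)

    leftover = dict(pool.density)  # non-participating classes keep everything
    fractions = {cid: 0.0 for cid in pool.density}
    zygotes: dict[tuple[str, str], float] = {}
    if fused > 0.0:
        fx = fused / nx0
        fy = fused / ny0
        x_share = {c: pool.density[c] / nx0 for c in x_ids}
        y_share = {c: pool.density[c] / ny0 for c in y_ids}
        for c in x_ids:
            leftover[c] = pool.density[c] * (1.0 - fx)
            fractions[c] = fx
        for c in y_ids:
            leftover[c] = pool.density[c] * (1.0 - fy)
            fractions[c] = fy
        for cx in x_ids:
            for cy in y_ids:
                zygotes[(cx, cy)] = fused * x_share[cx] * y_share[cy]
    return FertilizationResult(zygotes, leftover, fractions)


def fertilized_fraction_rare_mutant(
    resident_pool: GametePool, mutant_side: MatingType, phi: float
) -> float:
    """Probability that a vanishingly rare mutant gamete on ``mutant_side`` fuses.

    For ``phi=INFINITE``: 1 on the minority (or balanced) side; the ratio of
    opposite-side to own-side density on the majority side (scarce partners
    are allocated proportionally).  For finite phi: ``1 - exp(-∫ n_opp dt)``
    evaluated from the closed-form resident kinetics.
    """
    n_own = resident_pool.side_total(mutant_side)
    n_opp = resident_pool.side_total(mutant_side.other)
    if n_own <= 0.0:
        raise UndefinedFractionError(
            f"no resident gametes on side {mutant_side.value}; fraction undefined"
        )
    if math.isinf(phi):
        return 1.0 if n_own <= n_opp else n_opp / n_own
    if mutant_side is MatingType.X:
        own0, own_phi = n_own, remaining_after_kinetics(n_own, n_opp, phi)[0]
    else:
        own0, own_phi = n_own, remaining_after_kinetics(n_opp, n_own, phi)[1]
    # each gamete survives unfused with probability exp(-∫ n_opp dt) = own_phi/own0
    return 1.0 - own_phi / own0
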