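"""Domain types and life-history primitives.

The model describes a population of ``A`` haploid adults carrying one of two
self-incompatible mating types (X and Y).  Each generation every adult converts
its whole mass budget ``M`` into gametes of a heritable size ``m`` (so an adult
produces ``M/m`` gametes — the quality–quantity tradeoff), gametes of opposite
mating type fuse into zygotes during a fertilisation window, and both zygotes
and unfused gametes (parthenosporophytes) may survive to become the next adult
generation.  Survival follows a Vance function ``exp(-beta/size)``: a decaying
exponential in inverse propagule size, with separate scale parameters for the
zygotic (``beta_z``) and parthenogenetic (``beta_p``) routes.

This module holds the shared parameter/population containers plus the three
primitive operations: the two survival functions and gametogenesis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "INFINITE",
    "MatingType",
    "ReproductiveMode",
    "ModelParams",
    "AdultClass",
    "PopulationState",
    "zygote_survival",
    "parthenosporophyte_survival",
    "gamete_count",
    "AnisogamyError",
    "InvalidParameterError",
    "InvalidStrategyError",
    "PopulationCollapseError",
    "NotAtEquilibriumError",
    "RegimeError",
    "ConfigurationError",
    "UndefinedFractionError",
]

#: Distinguished value for ``phi`` (no kinetic limit on fertilisation: every
#: macrogamete fuses) and for ``beta_p`` (parthenogenesis impossible; the
#: obligate-sex limit).  Plain IEEE infinity so arithmetic limits work.
INFINITE = math.inf


class AnisogamyError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(AnisogamyError, ValueError):
    """A model parameter violates its domain (e.g. non-positive size)."""


class InvalidStrategyError(AnisogamyError, ValueError):
    """A gamete-size strategy is inviable (below the minimum gamete size)."""


class PopulationCollapseError(AnisogamyError, RuntimeError):
    """Every class died within one generation; the population is extinct."""


class NotAtEquilibriumError(AnisogamyError, ValueError):
    """An operation requiring a demographic equilibrium got a drifting state."""


class RegimeError(AnisogamyError, ValueError):
    """An analytic expression was evaluated outside its regime of validity."""


class ConfigurationError(AnisogamyError, ValueError):
    """A configuration file failed schema validation."""


class UndefinedFractionError(AnisogamyError, ZeroDivisionError):
    """A fertilised fraction was requested for an empty gamete side."""


class MatingType(str, enum.Enum):
    X = "X"
    Y = "Y"

    @property
    def other(self) -> "MatingType":
        return MatingType.Y if self is MatingType.X else MatingType.X


class ReproductiveMode(str, enum.Enum):
    SEXUAL = "SEXUAL"
    OBLIGATE_ASEXUAL = "OBLIGATE_ASEXUAL"


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidParameterError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Global constants of one scenario.

    Parameters
    ----------
    beta_z
        Zygote survival scale (mass units); larger means zygotes must be
        bigger to survive.
    beta_p
        Parthenosporophyte survival scale (mass units); ``INFINITE`` recovers
        obligate sex (unfused gametes never survive).
    phi
        Dimensionless fertilisation effort, the product of encounter rate and
        fertilisation period.  ``INFINITE`` is the gamete-competition regime
        in which every macrogamete is fertilised.
    M
        Adult mass budget, fully converted to gametes each generation.
    A
        Total adult population size enforced by density regulation.
    delta_m
        Mutational step size for gamete-size mutations.
    m_min
        Minimum viable gamete size; defaults to ``delta_m``.
    extinction_threshold
        Adult count below which a class is culled (the "finiteness" of the
        adult population in an otherwise deterministic model).
    max_generations
        Cap on generations per invasion / equilibration run.
    rng_seed
        Seed for stochastic trait-substitution runs.
    """

    beta_z: float
    beta_p: float
    phi: float = INFINITE
    M: float = 1.0
    A: float = 1000.0
    delta_m: float = 0.02
    m_min: float | None = None
    extinction_threshold: float = 1.0
    max_generations: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require_positive("beta_z", self.beta_z)
        _require_positive("beta_p", self.beta_p)
        if not self.phi >= 0:
            raise InvalidParameterError(f"phi must be >= 0, got {self.phi!r}")
        _require_positive("M", self.M)
        _require_positive("A", self.A)
        _require_positive("delta_m", self.delta_m)
        if self.m_min is None:
            object.__setattr__(self, "m_min", self.delta_m)
        elif not self.m_min > 0:
            raise InvalidParameterError(f"m_min must be > 0, got {self.m_min!r}")
        if self.extinction_threshold < 0:
            raise InvalidParameterError("extinction_threshold must be >= 0")
        if self.max_generations < 1:
            raise InvalidParameterError("max_generations must be >= 1")

    # -- flat-mapping serialisation (YAML/JSON friendly) -------------------

    _KEYS = (
        "beta_z",
        "beta_p",
        "phi",
        "M",
        "A",
        "delta_m",
        "m_min",
        "extinction_threshold",
        "max_generations",
        "rng_seed",
    )

    def to_dict(self) -> dict:
        out = {}
        for key in self._KEYS:
            value = getattr(self, key)
            if isinstance(value, float) and math.isinf(value):
                value = "inf"
            out[key] = value
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ModelParams":
        unknown = sorted(set(mapping) - set(cls._KEYS))
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {unknown}")
        missing = [k for k in ("beta_z", "beta_p") if k not in mapping]
        if missing:
            raise ConfigurationError(f"missing required parameter keys: {missing}")
        kwargs = {}
        for key, value in mapping.items():
            if isinstance(value, str):
                if value.lower() in {"inf", "infinite", "infinity"}:
                    value = INFINITE
                else:
                    try:
                        value = float(value)
                    except ValueError as exc:
                        raise ConfigurationError(
                            f"parameter {key!r} is not numeric: {value!r}"
                        ) from exc
            kwargs[key] = value
        for int_key in ("max_generations", "rng_seed"):
            if int_key in kwargs:
                kwargs[int_key] = int(kwargs[int_key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass
class AdultClass:
    """One heritable strategy: a mating type, a gamete size, a mode, a count.

    Obligately asexual classes retain their ancestral mating-type label for
    bookkeeping but it is never consulted during fertilisation.
    """

    class_id: str
    mating_type: MatingType
    mode: ReproductiveMode
    m: float
    count: float

    def __post_init__(self) -> None:
        self.mating_type = MatingType(self.mating_type)
        self.mode = ReproductiveMode(self.mode)
        _require_positive("m", self.m)
        if self.count < 0:
            raise InvalidParameterError(f"count must be >= 0, got {self.count!r}")

    @property
    def is_sexual(self) -> bool:
        return self.mode is ReproductiveMode.SEXUAL

    def copy(self) -> "AdultClass":
        return AdultClass(self.class_id, self.mating_type, self.mode, self.m, self.count)


@dataclass
class PopulationState:
    """The set of adult classes entering a generation."""

    classes: list[AdultClass]
    params: ModelParams
    generation_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"duplicate class ids: {ids}")

    @property
    def total(self) -> float:
        return sum(c.count for c in self.classes)

    @property
    def extant(self) -> list[AdultClass]:
        return [c for c in self.classes if c.count > 0]

    def frequencies(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c.class_id: 0.0 for c in self.classes}
        return {c.class_id: c.count / total for c in self.classes}

    def by_id(self, class_id: str) -> AdultClass:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    def _type_mean_size(self, mating_type: MatingType) -> float | None:
        """Count-weighted mean gamete size of the extant classes of one type."""
        num = den = 0.0
        for c in self.extant:
            if c.mating_type is mating_type:
                num += c.count * c.m
                den += c.count
        return num / den if den > 0 else None

    def asr(self, by: str = "size") -> float:
        """Adult sex ratio R in [0, 1].

        ``by="size"`` (default): proportion of adults belonging to the mating
        type with the strictly smaller gamete size (the microgamete producers);
        at exact size equality, or with one type absent, falls back to the
        ``by="y"`` convention (proportion of mating type Y).
        """
        total = self.total
        if total == 0:
            return 0.0
        y_count = sum(c.count for c in self.classes if c.mating_type is MatingType.Y)
        if by == "y":
            return y_count / total
        if by != "size":
            raise ValueError(f"unknown ASR convention {by!r}")
        mean_x = self._type_mean_size(MatingType.X)
        mean_y = self._type_mean_size(MatingType.Y)
        if mean_x is None or mean_y is None or mean_x == mean_y:
            return y_count / total
        micro = MatingType.Y if mean_y < mean_x else MatingType.X
        return sum(c.count for c in self.classes if c.mating_type is micro) / total

    def copy(self) -> "PopulationState":
        return PopulationState(
            [c.copy() for c in self.classes], self.params, self.generation_index
        )


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def zygote_survival(beta_z: float, m_i: float, m_j: float) -> float:
    """Survival probability of a zygote formed from gametes of size m_i, m_j.

    Vance function ``exp(-beta_z / (m_i + m_j))``: zygotes pool the mass of
    both gametes.  Evaluated via the exponent so that extreme exponents
    underflow gracefully to 0.0 instead of raising.
    """
    _require_positive("beta_z", beta_z)
    _require_positive("m_i", m_i)
    _require_positive("m_j", m_j)
    return math.exp(-beta_z / (m_i + m_j))


def parthenosporophyte_survival(beta_p: float, m_i: float) -> float:
    """Survival probability of an unfused gamete developing on its own.

    ``exp(-beta_p / m_i)``; exactly 0.0 when ``beta_p`` is ``INFINITE``
    (the obligate-sex limit where parthenogenesis is unprofitable).
    """
    _require_positive("m_i", m_i)
    if math.isinf(beta_p):
        return 0.0
    _require_positive("beta_p", beta_p)
    return math.exp(-beta_p / m_i)


def gamete_count(adult_count: float, M: float, m: float, m_min: float = 0.0) -> float:
    """Number of gametes produced by ``adult_count`` adults: ``adult_count*M/m``.

    Real-valued (expected value), not rounded.  Mass is conserved exactly:
    the product with ``m`` returns the total invested mass ``adult_count*M``.
    """
    if m < m_min:
        raise InvalidStrategyError(f"gamete size {m} below minimum viable size {m_min}")
    _require_positive("m", m)
    _require_positive("M", M)
    if adult_count < 0:
        raise InvalidParameterError(f"adult_count must be >= 0, got {adult_count!r}")
    return adult_count * M / m


def make_state(
    params: ModelParams,
    specs: Iterable[tuple[str, MatingType | str, ReproductiveMode | str, float, float]],
    generation_index: int = 0,
) -> PopulationState:
    """Convenience constructor from (id, mating_type, mode, m, count) tuples."""
    classes = [AdultClass(i, MatingType(t), ReproductiveMode(mo), m, n)
               for i, t, mo, m, n in specs]
    return PopulationState(classes, params, generation_index)


def two_type_state(
    params: ModelParams,
    mx: float,
    my: float,
    ax: float | None = None,
    ay: float | None = None,
) -> PopulationState:
    """A standard two-class sexual population (X of size mx, Y of size my)."""
    if ax is None:
        ax = params.A / 2
    if ay is None:
        ay = params.A - ax
    return make_state(
        params,
        [
            ("x", MatingType.X, ReproductiveMode.SEXUAL, mx, ax),
            ("y", MatingType.Y, ReproductiveMode.SEXUAL, my, ay),
        ],
    )
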