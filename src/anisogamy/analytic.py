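"""Closed-form adaptive-dynamics layer (gamete-competition regime, phi -> inf).

Everything here assumes the fertilisation window is effectively unlimited, so
all macrogametes fuse and only surplus microgametes take the parthenogenetic
route.  The layer provides:

* the equilibrium adult sex ratio ``R`` of a two-strategy resident population
  in closed form (the exact fixed point of the generation map);
* selection-gradient fields for three regimes — obligate sex (``beta_p`` at
  infinity), a single asexual/partnerless lineage, and the mixed regime where
  both sexual fusion and parthenogenesis contribute;
* invasion conditions for obligately asexual mutants arising on the micro- or
  macrogametic background;
* numerical fixed-point location/stability and state-space classification
  grids built on top of the gradient fields.

Gradients are derivatives of the log growth factor of a rare mutant in the
resident population, weighted by the resident frequency of the mutating type
(mutations arise at a fixed rate per adult, so the commoner type supplies
proportionally more mutations); the global mutation-rate constant is absorbed
into the rescaled time variable tau.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import INFINITE, InvalidParameterError, RegimeError

__all__ = [
    "GradientVector",
    "FixedPoint",
    "StateClassification",
    "Regime",
    "Stability",
    "asr_threshold",
    "equilibrium_asr",
    "gradient_obligate_sex",
    "gradient_asexual",
    "gradient_mixed",
    "mutant_log_growth",
    "rare_mutant_fertilized_fraction",
    "asexual_invasion_conditions",
    "find_fixed_points",
    "classify_grid",
    "integrate_trajectory",
]


@dataclass(frozen=True)
class GradientVector:
    """Selection gradients (mass per rescaled time) for the two types."""

    dmx_dtau: float
    dmy_dtau: float

    def __iter__(self):
        yield self.dmx_dtau
        yield self.dmy_dtau


class Regime(str, enum.Enum):
    OBLIGATE_SEX = "OBLIGATE_SEX"
    MIXED = "MIXED"
    ASEXUAL = "ASEXUAL"


class Stability(str, enum.Enum):
    STABLE = "STABLE"
    UNSTABLE = "UNSTABLE"
    SADDLE = "SADDLE"
    BOUNDARY = "BOUNDARY"
    MARGINAL = "MARGINAL"


@dataclass(frozen=True)
class FixedPoint:
    location: tuple[float, ...]
    stability: Stability
    regime: Regime
    eigenvalues: tuple[complex, ...] = ()


@dataclass(frozen=True)
class StateClassification:
    R: float
    macro_extinct: bool
    micro_asexual_invades: bool
    macro_asexual_invades: bool


def _check_sizes(mx: float, my: float) -> None:
    if not (mx > 0 and my > 0):
        raise InvalidParameterError(f"gamete sizes must be > 0, got ({mx}, {my})")


def asr_threshold(m_macro: float, m_micro: float, beta_z: float) -> float:
    """Critical parthenogenetic survival scale separating R < 1 from R = 1.

    Equals ``beta_z*m_micro/(m_macro+m_micro) - m_micro*log(m_micro/m_macro)``;
    when ``beta_p`` falls at or below it, surplus microgamete parthenogenesis
    outweighs the zygotic route and the macrogametic type is driven extinct.
    The same expression is the invasion condition for an obligately asexual
    mutant on the microgametic background.
    """
    s = m_macro + m_micro
    return beta_z * m_micro / s - m_micro * math.log(m_micro / m_macro)


def equilibrium_asr(mx: float, my: float, beta_z: float, beta_p: float) -> float:
    """Equilibrium proportion of the smaller-gamete (microgametic) type.

    Exact fixed point of the generation map in the gamete-competition limit.
    Returns 1/2 at isogamy (and in the obligate-sex limit ``beta_p`` infinite),
    and exactly 1 when parthenogenetic survival is weak enough that the
    macrogametic type cannot persist.  Symmetric under exchanging the two
    types: the larger-gamete type is always treated as the macrogamete.
    """
    _check_sizes(mx, my)
    if not beta_z > 0:
        raise InvalidParameterError(f"beta_z must be > 0, got {beta_z}")
    if mx == my or math.isinf(beta_p):
        return 0.5
    if not beta_p > 0:
        raise InvalidParameterError(f"beta_p must be > 0, got {beta_p}")
    m_macro, m_micro = (mx, my) if mx > my else (my, mx)
    if beta_p <= asr_threshold(m_macro, m_micro, beta_z):
        return 1.0
    s = m_macro + m_micro
    # ratio of zygotic to parthenogenetic survival weights; < m_micro/m_macro
    # in the interior regime, so no overflow is possible here
    z = math.exp(beta_z / s - beta_p / m_micro)
    return m_micro * (1.0 - z) / (2.0 * m_micro - s * z)


def _sex_kernel(m_self: float, s: float, beta_z: float) -> float:
    """d/dm of the log growth factor of a fully fertilised size mutant.

    Equals ``(beta_z*m - s^2) / (m * s^2)`` with ``s`` the zygote size.
    """
    return beta_z / (s * s) - 1.0 / m_self


def gradient_obligate_sex(mx: float, my: float, beta_z: float) -> GradientVector:
    """Selection gradients under obligate sex (no parthenogenesis).

    ``dm_i/dtau = (beta_z*m_i - (mx+my)^2) / (m_i*(mx+my)^2)`` for each type;
    the isogamous point at ``beta_z/4`` is unstable (a saddle of the joint
    field) and the extreme anisogamous states ``(beta_z, 0)``/``(0, beta_z)``
    are the attractors.
    """
    _check_sizes(mx, my)
    s = mx + my
    return GradientVector(_sex_kernel(mx, s, beta_z), _sex_kernel(my, s, beta_z))


def gradient_asexual(m: float, beta_p: float) -> float:
    """Selection gradient of progeny size in a purely parthenogenetic lineage.

    ``dm/dtau = (beta_p - m)/m^2``; the unique interior attractor is the
    optimal independent progeny size ``m* = beta_p``.
    """
    if not m > 0:
        raise InvalidParameterError(f"m must be > 0, got {m}")
    return (beta_p - m) / (m * m)


def rare_mutant_fertilized_fraction(
    mx: float, my: float, beta_z: float, beta_p: float
) -> float:
    """Fertilised fraction F of a rare microgametic-side mutant at resident
    equilibrium: opposite-side density over own-side density,
    ``(1-R)*m_micro / (R*m_macro)``."""
    R = equilibrium_asr(mx, my, beta_z, beta_p)
    if R >= 1.0:
        raise RegimeError("macrogametes extinct (R=1); fraction undefined")
    m_macro, m_micro = (mx, my) if mx > my else (my, mx)
    return (1.0 - R) * m_micro / (R * m_macro)


def mutant_log_growth(
    m_hat: float, m_macro: float, F: float, beta_z: float, beta_p: float
) -> float:
    """Log per-capita growth factor of a rare microgametic-side mutant of
    size ``m_hat``: gamete number times the F-weighted mixture of zygotic and
    parthenogenetic survival,
    ``log[(F*exp(-beta_z/(m_macro+m_hat)) + (1-F)*exp(-beta_p/m_hat)) / m_hat]``.
    """
    wz = F * math.exp(-beta_z / (m_macro + m_hat))
    wp = (1.0 - F) * math.exp(-beta_p / m_hat) if not math.isinf(beta_p) else 0.0
    return math.log(wz + wp) - math.log(m_hat)


def _micro_kernel(
    m_micro: float, m_macro: float, F: float, beta_z: float, beta_p: float
) -> float:
    """Exact derivative of :func:`mutant_log_growth` with respect to mutant size."""
    s = m_macro + m_micro
    wz = F * math.exp(-beta_z / s)
    wp = (1.0 - F) * math.exp(-beta_p / m_micro) if not math.isinf(beta_p) else 0.0
    total = wz + wp
    if total <= 0.0:
        # both survival routes underflow; fall back to the dominant (zygotic)
        # route, whose log-derivative is the obligate-sex kernel
        return _sex_kernel(m_micro, s, beta_z)
    num = wz * beta_z / (s * s) + (
        wp * beta_p / (m_micro * m_micro) if wp > 0.0 else 0.0
    )
    return num / total - 1.0 / m_micro


def gradient_mixed(
    mx: float, my: float, beta_z: float, beta_p: float
) -> GradientVector:
    """Selection gradients when both sexual and parthenogenetic routes exist.

    Macrogamete component: the obligate-sex kernel weighted by the resident
    macrogamete frequency ``1 - R`` (macrogametes are always fully fertilised
    in this regime, so only the mutation supply changes).  Microgamete
    component: ``R`` times the derivative of the rare-mutant log growth
    factor, in which a fraction ``F`` of mutant gametes fuse and the rest
    attempt parthenogenesis.  Requires both types extant (``0 < R < 1``).
    """
    _check_sizes(mx, my)
    R = equilibrium_asr(mx, my, beta_z, beta_p)
    if R >= 1.0:
        raise RegimeError(
            "macrogametes extinct (R=1); use gradient_asexual for the survivor"
        )
    s = mx + my
    if mx == my:
        half = 0.5 * _sex_kernel(mx, s, beta_z)
        return GradientVector(half, half)
    m_macro, m_micro = (mx, my) if mx > my else (my, mx)
    F = (1.0 - R) * m_micro / (R * m_macro)
    d_macro = (1.0 - R) * _sex_kernel(m_macro, s, beta_z)
    d_micro = R * _micro_kernel(m_micro, m_macro, F, beta_z, beta_p)
    if mx > my:
        return GradientVector(d_macro, d_micro)
    return GradientVector(d_micro, d_macro)


def asexual_invasion_conditions(
    mx: float, my: float, beta_z: float, beta_p: float
) -> tuple[bool, bool]:
    """Can an obligately asexual mutant invade the resident equilibrium?

    Returns ``(micro_invades, macro_invades)``.  A microgametic asexual
    invades iff the sex-ratio threshold exceeds ``beta_p`` (the same condition
    under which microgametes drive macrogametes extinct without any asexual
    mutation).  A macrogametic asexual invades iff
    ``beta_z*m_macro/(m_macro+m_micro) > beta_p`` while macrogametes still
    exist in the resident population (``R < 1``).
    """
    _check_sizes(mx, my)
    if math.isinf(beta_p):
        return (False, False)
    m_macro, m_micro = (mx, my) if mx >= my else (my, mx)
    if mx == my:
        thr = beta_z / 2.0  # isogamous limit of the threshold expression
    else:
        thr = asr_threshold(m_macro, m_micro, beta_z)
    micro = thr > beta_p
    macro = (beta_z * m_macro / (m_macro + m_micro) > beta_p) and (beta_p > thr)
    return micro, macro


# ---------------------------------------------------------------------------
# Fixed points, stability, classification grids
# ---------------------------------------------------------------------------


def _field(regime: Regime, beta_z: float, beta_p: float):
    if regime is Regime.OBLIGATE_SEX:
        def f(v):
            return np.array(list(gradient_obligate_sex(v[0], v[1], beta_z)))
    elif regime is Regime.MIXED:
        def f(v):
            return np.array(list(gradient_mixed(v[0], v[1], beta_z, beta_p)))
    else:
        raise RegimeError(f"no planar gradient field for regime {regime}")
    return f


def _jacobian(f, v: np.ndarray, h: float = 1e-6) -> np.ndarray:
    n = len(v)
    J = np.empty((n, n))
    for j in range(n):
        dv = np.zeros(n)
        dv[j] = h
        J[:, j] = (f(v + dv) - f(v - dv)) / (2.0 * h)
    return J


def _classify(eigvals: np.ndarray, marginal_tol: float = 1e-8) -> Stability:
    re = eigvals.real
    if np.max(np.abs(re)) < marginal_tol:
        return Stability.MARGINAL
    if np.all(re < 0):
        return Stability.STABLE
    if np.all(re > 0):
        return Stability.UNSTABLE
    return Stability.SADDLE


def find_fixed_points(
    beta_z: float,
    beta_p: float,
    regime: Regime = Regime.MIXED,
    box: tuple[float, float] = (0.01, 2.0),
    n_starts: int = 8,
    dedupe_tol: float = 1e-6,
    boundary_floor: float = 1e-4,
) -> list[FixedPoint]:
    """Locate fixed points of the selection-gradient field and classify them.

    Multi-start root finding on an ``n_starts`` x ``n_starts`` lattice inside
    ``box`` (plus an explicit scan of the isogamous diagonal, where symmetric
    roots live), deduplicated at ``dedupe_tol``.  Stability comes from the
    eigenvalues of a central-difference Jacobian.  Boundary attractors — the
    extreme anisogamous states where the micro trait runs into its floor —
    are found by scanning the macro component along the box edge and are
    tagged ``BOUNDARY``.
    """
    regime = Regime(regime)
    lo, hi = box
    if regime is Regime.ASEXUAL:
        points = []
        if lo <= beta_p <= hi:
            slope = -1.0 / (beta_p * beta_p)  # d/dm of (beta_p-m)/m^2 at m=beta_p
            points.append(
                FixedPoint((beta_p,), Stability.STABLE, regime, (complex(slope),))
            )
        return points

    f = _field(regime, beta_z, beta_p)

    def safe(v):
        try:
            return f(v)
        except (RegimeError, InvalidParameterError):
            return None

    found: list[np.ndarray] = []

    def record(v):
        g = safe(v)
        if g is None or np.max(np.abs(g)) > 1e-8:
            return
        for w in found:
            if np.max(np.abs(v - w)) < dedupe_tol:
                return
        found.append(np.asarray(v, float))

    # diagonal scan (handles the isogamous root exactly on the symmetry line)
    def diag(m):
        g = safe((m, m))
        return math.nan if g is None else g[0]

    grid = np.linspace(lo, hi, 200)
    vals = [diag(m) for m in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if math.isnan(fa) or math.isnan(fb) or fa * fb > 0:
            continue
        m = optimize.brentq(diag, a, b, xtol=1e-13)
        record(np.array([m, m]))

    # planar multistart
    starts = np.linspace(lo, hi, n_starts)
    for sx in starts:
        for sy in starts:
            if safe((sx, sy)) is None:
                continue
            sol = optimize.root(
                lambda v: (safe(v) if safe(v) is not None else np.array([1e6, 1e6])),
                np.array([sx, sy]),
                method="hybr",
                options={"xtol": 1e-12},
            )
            v = sol.x
            if sol.success and lo - 1e-9 <= v[0] <= hi + 1e-9 and lo - 1e-9 <= v[1] <= hi + 1e-9:
                record(v)

    points = []
    for v in found:
        J = _jacobian(f, v)
        eig = np.linalg.eigvals(J)
        points.append(FixedPoint(tuple(v), _classify(eig), regime, tuple(eig)))

    # boundary attractors: micro trait pinned at the floor, macro component zero
    def macro_edge(mm, micro_is_y=True):
        g = safe((mm, boundary_floor) if micro_is_y else (boundary_floor, mm))
        if g is None:
            return math.nan
        return g[0] if micro_is_y else g[1]

    for micro_is_y in (True, False):
        vals = [macro_edge(mm, micro_is_y) for mm in grid]
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if math.isnan(fa) or math.isnan(fb) or fa * fb > 0:
                continue
            mm = optimize.brentq(lambda t: macro_edge(t, micro_is_y), a, b, xtol=1e-13)
            loc = (mm, 0.0) if micro_is_y else (0.0, mm)
            if any(
                max(abs(loc[0] - p.location[0]), abs(loc[1] - p.location[1]))
                < dedupe_tol
                for p in points
            ):
                continue
            points.append(FixedPoint(loc, Stability.BOUNDARY, regime))
    return points


def classify_state(mx: float, my: float, beta_z: float, beta_p: float) -> StateClassification:
    R = equilibrium_asr(mx, my, beta_z, beta_p)
    micro, macro = asexual_invasion_conditions(mx, my, beta_z, beta_p)
    return StateClassification(R, R >= 1.0, micro, macro)


def classify_grid(
    mx_values,
    my_values,
    beta_z: float,
    beta_p: float,
) -> pd.DataFrame:
    """Evaluate the equilibrium ASR and asexual-invasion conditions on a
    rectangular (mx, my) lattice; returns a tidy DataFrame with columns
    mx, my, R, macro_extinct, micro_asex, macro_asex."""
    rows = []
    for mx in np.asarray(mx_values, float):
        for my in np.asarray(my_values, float):
            c = classify_state(mx, my, beta_z, beta_p)
            rows.append(
                (mx, my, c.R, c.macro_extinct, c.micro_asexual_invades,
                 c.macro_asexual_invades)
            )
    return pd.DataFrame(
        rows, columns=["mx", "my", "R", "macro_extinct", "micro_asex", "macro_asex"]
    )


def integrate_trajectory(
    mx0: float,
    my0: float,
    beta_z: float,
    beta_p: float,
    t_max: float = 50.0,
    m_min: float = 0.02,
    max_step: float = 0.05,
) -> pd.DataFrame:
    """Integrate the mixed-regime gradient flow from (mx0, my0).

    Stops (and, where appropriate, switches to the single-type asexual flow
    toward ``m* = beta_p``) when either trait hits the minimum gamete size or
    the trajectory crosses into the macrogamete-extinction region (R = 1).
    Returns a DataFrame with columns t, mx, my, R, regime; after a switch the
    surviving type's trait continues and the lost type's column holds NaN.
    """
    from scipy.integrate import solve_ivp

    def rhs(_t, v):
        # trial steps of the integrator may overshoot the event boundaries
        # (size floor, extinction region) before the event root-finder clamps,
        # so evaluate on a clamped point and extend continuously into R=1:
        # macrogamete selection vanishes with 1-R and the microgamete follows
        # the pure parthenogenetic gradient
        mx, my = (max(v[0], 1e-9), max(v[1], 1e-9))
        try:
            return list(gradient_mixed(mx, my, beta_z, beta_p))
        except RegimeError:
            if mx >= my:
                return [0.0, gradient_asexual(my, beta_p)]
            return [gradient_asexual(mx, beta_p), 0.0]

    def hit_floor(_t, v):
        return min(v[0], v[1]) - m_min

    hit_floor.terminal = True

    def hit_extinction(_t, v):
        m_macro, m_micro = (v[0], v[1]) if v[0] >= v[1] else (v[1], v[0])
        if v[0] == v[1]:
            return beta_p - beta_z / 2.0
        return beta_p - asr_threshold(m_macro, m_micro, beta_z)

    hit_extinction.terminal = True
    hit_extinction.direction = -1.0

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [mx0, my0],
        events=[hit_floor, hit_extinction],
        max_step=max_step,
        rtol=1e-8,
        atol=1e-10,
    )
    rows = [
        (t, x, y, equilibrium_asr(x, y, beta_z, beta_p), "MIXED")
        for t, (x, y) in zip(sol.t, sol.y.T)
    ]
    t_end = sol.t[-1]
    if sol.status == 1 and len(sol.t_events[1]) and t_end < t_max:
        # macrogametes extinct: survivor is the micro type, Eq-7-style flow
        x_end, y_end = sol.y[:, -1]
        micro_is_y = y_end < x_end
        m = min(x_end, y_end)
        single = solve_ivp(
            lambda _t, v: [gradient_asexual(v[0], beta_p)],
            (t_end, t_max),
            [m],
            max_step=max_step,
            rtol=1e-8,
            atol=1e-10,
        )
        for t, mm in zip(single.t, single.y[0]):
            rows.append(
                (t, math.nan, mm, 1.0, "ASEXUAL")
                if micro_is_y
                else (t, mm, math.nan, 1.0, "ASEXUAL")
            )
    return pd.DataFrame(rows, columns=["t", "mx", "my", "R", "regime"])
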