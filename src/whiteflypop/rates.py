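"""Daily vital rates for the four-stage whitefly life cycle.

The projection model runs on a daily time step with four stages — egg,
nymph (the four instars pooled), pupa (red-eyed fourth instar) and adult.
Each immature stage is a stay/advance/die chain: every day an individual
advances with probability ``r``, dies with probability ``d`` and stays with
probability ``s = 1 - r - d``.  This module converts laboratory life-table
measurements into those daily probabilities, pools the nymph instars,
calibrates the field-mortality adjustment ``q`` against an observed adult
emergence fraction, and translates per-generation kill fractions measured
in whole-plant bioassays into daily mortality increments.

Conversion rules
----------------
* daily development rate: ``r = 1/m`` with ``m`` the median development
  time in days;
* daily mortality rate: ``d = 1 - stage survival``;
* nymph pooling over instar durations ``T1..T4`` and instar mortalities
  ``N1..N4``: ``r2 = (T1+T2+T3+T4)**-1`` and
  ``d2 = (T1*N1 + T2*N2 + T3*N3 + T4*N4) / (T1+T2+T3+T4)``;
* field adjustment: a single additive daily mortality ``q`` applied to
  egg, nymph and pupa stages, solved so that the egg-to-adult emergence
  probability matches an observed field value (~10%);
* treatment: a per-generation kill fraction ``P`` becomes the daily
  increment ``1 - (1-P)**(1/g)`` with ``g`` the generation length in days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import bisect

from .exceptions import (
    DegenerateRatesError,
    DomainError,
    InconsistentLifeTableError,
    InfeasibleTargetError,
)

__all__ = [
    "IMMATURE_STAGES",
    "LifeTable",
    "DailyRates",
    "TreatmentSpec",
    "daily_development_rate",
    "daily_mortality_rate",
    "aggregate_nymph",
    "life_table_to_daily_rates",
    "emergence_probability",
    "with_field_adjustment",
    "calibrate_field_adjustment",
    "apply_treatment",
    "generation_time",
    "simulate_cohort",
]

IMMATURE_STAGES = ("egg", "nymph", "pupa")


@dataclass(frozen=True)
class LifeTable:
    """Laboratory stage measurements at a single temperature.

    Parameters
    ----------
    temperature : float
        Rearing temperature in degrees Celsius.
    m_egg, m_pupa : float
        Median development time of the egg and pupal stage, in days.
    nymph_durations : tuple of four floats
        ``T1..T4``: median time (days) spent in each nymphal instar.
    egg_survival, pupa_survival : float
        Fraction of the cohort surviving the whole stage, in ``(0, 1]``.
    nymph_survivals : tuple of four floats
        Per-instar survival fractions (complements of the instar
        mortalities ``N1..N4``).
    adult_daily_survival : float
        Daily survival probability of adults, in ``(0, 1]``.
    fecundity : float
        Eggs laid per adult per day (>= 0).
    """

    temperature: float
    m_egg: float
    m_pupa: float
    nymph_durations: tuple[float, float, float, float]
    egg_survival: float
    nymph_survivals: tuple[float, float, float, float]
    pupa_survival: float
    adult_daily_survival: float
    fecundity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nymph_durations", tuple(float(x) for x in self.nymph_durations))
        object.__setattr__(self, "nymph_survivals", tuple(float(x) for x in self.nymph_survivals))
        if len(self.nymph_durations) != 4 or len(self.nymph_survivals) != 4:
            raise DomainError("expected exactly four nymphal instars")
        for m in (self.m_egg, self.m_pupa, *self.nymph_durations):
            if m < 1.0:
                raise DomainError(f"median development time {m} must be >= 1 day")
        for s in (self.egg_survival, self.pupa_survival, self.adult_daily_survival,
                  *self.nymph_survivals):
            if not 0.0 < s <= 1.0:
                raise DomainError(f"survival fraction {s} must lie in (0, 1]")
        if self.fecundity < 0.0:
            raise DomainError("fecundity must be non-negative")


@dataclass(frozen=True)
class DailyRates:
    """Daily transition probabilities at one temperature.

    ``r_*`` are daily development (advance) probabilities, ``d_*`` daily
    mortality probabilities; the stay probability of each immature stage is
    the derived ``s_* = 1 - (r_* + d_*)`` so the three always sum to one.
    """

    temperature: float
    r_egg: float
    d_egg: float
    r_nymph: float
    d_nymph: float
    r_pupa: float
    d_pupa: float
    d_adult: float
    fecundity: float

    def __post_init__(self) -> None:
        for name in ("r_egg", "d_egg", "r_nymph", "d_nymph", "r_pupa", "d_pupa", "d_adult"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name}={p} is not a probability")
        for stage, (r, d) in zip(IMMATURE_STAGES, self.immature_pairs()):
            if r + d > 1.0:
                raise DomainError(f"{stage}: r + d = {r + d} exceeds 1")
        if self.fecundity < 0.0:
            raise DomainError("fecundity must be non-negative")

    # stay probabilities, defined so that (r + d) + s == 1.0 holds exactly
    # in floating point (s is the rounded complement of the rounded sum)
    @property
    def s_egg(self) -> float:
        return 1.0 - (self.r_egg + self.d_egg)

    @property
    def s_nymph(self) -> float:
        return 1.0 - (self.r_nymph + self.d_nymph)

    @property
    def s_pupa(self) -> float:
        return 1.0 - (self.r_pupa + self.d_pupa)

    def immature_pairs(self) -> tuple[tuple[float, float], ...]:
        """(r, d) for egg, nymph, pupa, in stage order."""
        return (
            (self.r_egg, self.d_egg),
            (self.r_nymph, self.d_nymph),
            (self.r_pupa, self.d_pupa),
        )


@dataclass(frozen=True)
class TreatmentSpec:
    """Per-generation kill fractions measured on transgenic plants.

    ``P_A`` (adults) and ``P_L`` (nymphs) are the fractions eliminated over
    one generation of ``g`` days; both lie in ``[0, 1]``.
    """

    P_A: float
    P_L: float
    g: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_A <= 1.0 or not 0.0 <= self.P_L <= 1.0:
            raise DomainError("kill fractions must lie in [0, 1]")
        if self.g < 1:
            raise DomainError("generation length must be at least one day")


def daily_development_rate(m: float) -> float:
    """Daily probability of advancing a stage whose median duration is ``m`` days."""
    if m < 1.0:
        raise DomainError(f"median development time {m} must be >= 1 day")
    return 1.0 / m


def daily_mortality_rate(stage_survival: float) -> float:
    """Daily mortality ``d = 1 - survival`` from a stage survival fraction."""
    if not 0.0 < stage_survival <= 1.0:
        raise DomainError(f"stage survival {stage_survival} must lie in (0, 1]")
    return 1.0 - stage_survival


def aggregate_nymph(
    durations: Sequence[float], mortalities: Sequence[float]
) -> tuple[float, float, float]:
    """Pool the four nymphal instars into one model stage.

    Parameters
    ----------
    durations : ``T1..T4`` instar durations in days (each >= 1).
    mortalities : ``N1..N4`` instar mortality fractions in ``[0, 1)``.

    Returns
    -------
    (r2, d2, s2) : the pooled daily development, mortality and stay
    probabilities; ``r2`` is the reciprocal of the total nymphal duration
    and ``d2`` the duration-weighted mean instar mortality.
    """
    if len(durations) != 4 or len(mortalities) != 4:
        raise DomainError("expected four instar durations and four mortalities")
    for t in durations:
        if t < 1.0:
            raise DomainError(f"instar duration {t} must be >= 1 day")
    for n in mortalities:
        if not 0.0 <= n < 1.0:
            raise DomainError(f"instar mortality {n} must lie in [0, 1)")
    total = float(sum(durations))
    r2 = 1.0 / total
    d2 = float(sum(t * n for t, n in zip(durations, mortalities))) / total
    if r2 + d2 > 1.0:
        raise InconsistentLifeTableError(
            f"pooled nymph rates r2 + d2 = {r2 + d2:.4f} exceed 1"
        )
    return r2, d2, 1.0 - (r2 + d2)


def life_table_to_daily_rates(table: LifeTable) -> DailyRates:
    """Convert one laboratory life table into daily transition probabilities."""
    r1 = daily_development_rate(table.m_egg)
    d1 = daily_mortality_rate(table.egg_survival)
    if r1 + d1 > 1.0:
        raise InconsistentLifeTableError("egg: r + d exceeds 1")
    r2, d2, _ = aggregate_nymph(
        table.nymph_durations, tuple(1.0 - s for s in table.nymph_survivals)
    )
    r3 = daily_development_rate(table.m_pupa)
    d3 = daily_mortality_rate(table.pupa_survival)
    if r3 + d3 > 1.0:
        raise InconsistentLifeTableError("pupa: r + d exceeds 1")
    return DailyRates(
        temperature=table.temperature,
        r_egg=r1, d_egg=d1,
        r_nymph=r2, d_nymph=d2,
        r_pupa=r3, d_pupa=d3,
        d_adult=daily_mortality_rate(table.adult_daily_survival),
        fecundity=table.fecundity,
    )


def emergence_probability(rates: DailyRates) -> float:
    """Probability that an egg eventually emerges as an adult.

    In a stay/advance/die chain the probability of ever leaving a stage
    alive is ``r / (r + d)``; egg-to-adult emergence is the product over
    the three immature stages.
    """
    p = 1.0
    for stage, (r, d) in zip(IMMATURE_STAGES, rates.immature_pairs()):
        if r + d == 0.0:
            raise DegenerateRatesError(f"{stage}: r + d = 0, fate undefined")
        p *= r / (r + d)
    return p


def with_field_adjustment(rates: DailyRates, q: float) -> DailyRates:
    """Add the field mortality ``q`` to each immature stage's daily mortality."""
    if q < 0.0:
        raise DomainError("field adjustment q must be non-negative")
    return dataclasses.replace(
        rates,
        d_egg=rates.d_egg + q,
        d_nymph=rates.d_nymph + q,
        d_pupa=rates.d_pupa + q,
    )


def calibrate_field_adjustment(
    rates: DailyRates, target_emergence: float = 0.10, *, xtol: float = 1e-12
) -> float:
    """Solve for the daily field mortality ``q`` matching a field emergence rate.

    Laboratory survival overstates field survival; a single additive daily
    mortality ``q`` is applied uniformly to egg, nymph and pupa stages and
    solved by bisection so that :func:`emergence_probability` equals
    ``target_emergence`` (default 10%, the observed field adult emergence).

    Returns ``q >= 0``.  Raises :class:`InfeasibleTargetError` when the
    target exceeds the unadjusted emergence or lies below the emergence at
    the largest feasible ``q`` (the value at which some stage's stay
    probability reaches zero).
    """
    if not 0.0 < target_emergence <= 1.0:
        raise DomainError("target emergence must lie in (0, 1]")
    baseline = emergence_probability(rates)
    if target_emergence > baseline:
        raise InfeasibleTargetError(
            f"target emergence {target_emergence} exceeds unadjusted emergence {baseline:.4f}"
        )
    if target_emergence == baseline:
        return 0.0
    q_max = min(1.0 - (r + d) for r, d in rates.immature_pairs())
    floor = emergence_probability(with_field_adjustment(rates, q_max))
    if target_emergence < floor:
        raise InfeasibleTargetError(
            f"target emergence {target_emergence} below reachable floor {floor:.4g}"
        )

    def gap(q: float) -> float:
        return emergence_probability(with_field_adjustment(rates, q)) - target_emergence

    return float(bisect(gap, 0.0, q_max, xtol=xtol))


def apply_treatment(rates: DailyRates, treatment: TreatmentSpec) -> DailyRates:
    """Add treatment mortality from per-generation kill fractions.

    A fraction ``P_A`` of adults and ``P_L`` of nymphs eliminated per
    generation of ``g`` days corresponds to the daily mortality increments
    ``1 - (1-P)**(1/g)``, added to the adult and nymph daily mortalities.
    Probabilities are capped so each stage's stay probability stays
    non-negative (eggs and pupae are untouched: the bioassays measured
    adult survival and nymph development only).
    """
    extra_a = 1.0 - (1.0 - treatment.P_A) ** (1.0 / treatment.g)
    extra_l = 1.0 - (1.0 - treatment.P_L) ** (1.0 / treatment.g)
    return dataclasses.replace(
        rates,
        d_adult=min(1.0, rates.d_adult + extra_a),
        d_nymph=min(1.0 - rates.r_nymph, rates.d_nymph + extra_l),
    )


def generation_time(rates: DailyRates) -> int:
    """Expected egg-to-adult development time, in whole days.

    Computed as the sum over immature stages of the expected stage duration
    ``1/r``, rounded to the nearest day.  Used as the generation length
    ``g`` when converting per-generation kill fractions to daily rates.
    """
    total = 0.0
    for stage, (r, _) in zip(IMMATURE_STAGES, rates.immature_pairs()):
        if r == 0.0:
            raise DegenerateRatesError(f"{stage}: r = 0, development never completes")
        total += 1.0 / r
    return int(round(total))


def simulate_cohort(
    rates: DailyRates, n: int = 100_000, seed: int = 0, max_days: int = 100_000
) -> float:
    """Monte-Carlo fraction of ``n`` eggs that reach adulthood.

    Follows each individual day by day through the stay/advance/die chain;
    serves as a stochastic cross-check of :func:`emergence_probability`.
    """
    if n < 1:
        raise DomainError("cohort size must be positive")
    rng = np.random.default_rng(seed)
    r = np.array([rates.r_egg, rates.r_nymph, rates.r_pupa])
    d = np.array([rates.d_egg, rates.d_nymph, rates.d_pupa])
    if np.any(r + d == 0.0):
        raise DegenerateRatesError("some immature stage has r + d = 0")
    stage = np.zeros(n, dtype=np.int8)  # 0 egg, 1 nymph, 2 pupa, 3 adult, -1 dead
    for _ in range(max_days):
        active = (stage >= 0) & (stage < 3)
        if not active.any():
            break
        cur = stage[active]
        u = rng.random(cur.size)
        new = cur.copy()
        new[u < r[cur]] += 1          # advance
        new[u >= 1.0 - d[cur]] = -1   # die (disjoint from advance since r + d <= 1)
        stage[active] = new
    return float(np.mean(stage == 3))
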