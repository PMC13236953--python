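"""Daily Leslie-matrix dynamics for a single whitefly population.

The population state is a vector of (eggs, nymphs, pupae, adults) per
leaf.  Each day the state is multiplied by a temperature-specific 4x4
projection matrix, then a density-dependent amount ``gamma * adults**2``
is subtracted from the adult class so the population saturates at a
carrying capacity instead of growing exponentially.  Matrices are built at
five anchor temperatures (16/20/24/28/32 degC by default) and linearly
interpolated element-wise at the day's mean temperature; temperatures
outside the anchor range are clamped to the nearest anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .exceptions import (
    ConfigurationError,
    DomainError,
    InfeasibleCalibrationError,
    InputLengthError,
)
from .rates import DailyRates, TreatmentSpec, apply_treatment

__all__ = [
    "STAGES",
    "PopulationState",
    "StageMatrix",
    "ModelParams",
    "build_matrix",
    "interpolate_matrix",
    "step",
    "simulate",
    "calibrate_density_dependence",
]

STAGES = ("eggs", "nymphs", "pupae", "adults")
DEFAULT_INITIAL_STATE = (0.0, 0.0, 0.0, 1.0)  # one colonising adult per leaf


@dataclass(frozen=True)
class PopulationState:
    """Stage abundances (individuals per leaf) on a given day."""

    eggs: float
    nymphs: float
    pupae: float
    adults: float
    day: int = 0

    def __post_init__(self) -> None:
        if min(self.eggs, self.nymphs, self.pupae, self.adults) < 0.0:
            raise DomainError("stage abundances must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.eggs, self.nymphs, self.pupae, self.adults], dtype=float)

    @classmethod
    def from_array(cls, v: Sequence[float], day: int = 0) -> "PopulationState":
        e, n, p, a = (float(x) for x in v)
        return cls(e, n, p, a, day)


@dataclass(frozen=True)
class StageMatrix:
    """A 4x4 daily projection matrix tagged with its temperature."""

    values: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4, 4):
            raise DomainError(f"stage matrix must be 4x4, got {v.shape}")
        if np.any(v < 0.0):
            raise DomainError("stage matrix entries must be non-negative")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


def build_matrix(rates: DailyRates) -> StageMatrix:
    """Assemble the daily projection matrix from daily rates.

    Diagonal entries are stay probabilities (adults: daily survival), the
    subdiagonal holds advance probabilities, and the top-right entry is the
    daily fecundity.
    """
    M = np.zeros((4, 4))
    M[0, 0] = rates.s_egg
    M[1, 0] = rates.r_egg
    M[1, 1] = rates.s_nymph
    M[2, 1] = rates.r_nymph
    M[2, 2] = rates.s_pupa
    M[3, 2] = rates.r_pupa
    M[3, 3] = 1.0 - rates.d_adult
    M[0, 3] = rates.fecundity
    return StageMatrix(M, rates.temperature)


def _interpolate_values(
    anchor_temps: Sequence[float], anchor_values: Sequence[np.ndarray], T: float
) -> np.ndarray:
    """Element-wise linear interpolation between bracketing anchors.

    Shared by the 4x4 and 8x8 simulators so both produce bit-identical
    entries for the same anchors.  ``T`` outside the range is clamped.
    """
    if T <= anchor_temps[0]:
        return np.array(anchor_values[0], dtype=float)
    if T >= anchor_temps[-1]:
        return np.array(anchor_values[-1], dtype=float)
    hi = int(np.searchsorted(anchor_temps, T))
    lo = hi - 1
    if anchor_temps[hi] == T:
        return np.array(anchor_values[hi], dtype=float)
    w = (T - anchor_temps[lo]) / (anchor_temps[hi] - anchor_temps[lo])
    return (1.0 - w) * anchor_values[lo] + w * anchor_values[hi]


def interpolate_matrix(anchors: Sequence[StageMatrix], T: float) -> StageMatrix:
    """Interpolate the projection matrix at temperature ``T``.

    Uses the fractional distance between the two bracketing anchor
    matrices; exact at anchors, clamped outside the anchor range.
    """
    if len(anchors) < 2:
        raise ConfigurationError("need at least two anchor matrices")
    temps = [a.temperature for a in anchors]
    if sorted(temps) != temps:
        raise ConfigurationError("anchor matrices must be sorted by temperature")
    values = _interpolate_values(temps, [a.values for a in anchors], T)
    return StageMatrix(values, T)


def _apply_density(v: np.ndarray, adult_index: int, gamma: float) -> None:
    a = v[adult_index]
    v[adult_index] = a - gamma * a * a


def step(state: np.ndarray, matrix: StageMatrix | np.ndarray, gamma: float) -> np.ndarray:
    """Advance the population one day.

    Matrix multiplication (reproduction, stage advance, survival) first,
    then the density-dependent subtraction ``gamma * adults**2`` from the
    adult class; every component is clamped at zero.
    """
    if gamma < 0.0:
        raise DomainError("gamma must be non-negative")
    M = matrix.values if isinstance(matrix, StageMatrix) else np.asarray(matrix, dtype=float)
    v = M @ np.asarray(state, dtype=float)
    _apply_density(v, 3, gamma)
    np.maximum(v, 0.0, out=v)
    return v


@dataclass(frozen=True)
class ModelParams:
    """Everything a simulation needs besides the temperature series.

    ``anchor_rates`` are the (field-adjusted) daily rates at the anchor
    temperatures, sorted ascending; ``gamma`` is the density-dependence
    coefficient (per individuals-per-leaf per day); ``carrying_capacity``
    is the calibration target it was fitted to.
    """

    anchor_rates: tuple[DailyRates, ...]
    gamma: float
    carrying_capacity: float = 500.0
    initial_state: tuple[float, float, float, float] = DEFAULT_INITIAL_STATE
    horizon: int = 730

    def __post_init__(self) -> None:
        if len(self.anchor_rates) < 2:
            raise ConfigurationError("need at least two anchor temperatures")
        temps = [r.temperature for r in self.anchor_rates]
        if sorted(temps) != temps:
            raise ConfigurationError("anchor rates must be sorted by temperature")
        if self.gamma < 0.0:
            raise DomainError("gamma must be non-negative")
        if self.carrying_capacity <= 0.0:
            raise DomainError("carrying capacity must be positive")
        if self.horizon < 0:
            raise DomainError("horizon must be non-negative")
        object.__setattr__(self, "initial_state", tuple(float(x) for x in self.initial_state))
        if min(self.initial_state) < 0.0:
            raise DomainError("initial abundances must be non-negative")

    def anchor_matrices(self, treatment: TreatmentSpec | None = None) -> tuple[StageMatrix, ...]:
        """Projection matrices at the anchors, optionally with treatment applied."""
        rates = self.anchor_rates
        if treatment is not None:
            rates = tuple(apply_treatment(r, treatment) for r in rates)
        return tuple(build_matrix(r) for r in rates)


def simulate(
    params: ModelParams,
    temps: Sequence[float],
    treatment: TreatmentSpec | None = None,
) -> pd.DataFrame:
    """Simulate daily dynamics driven by a temperature series.

    Returns a DataFrame with columns ``day``, ``temperature`` (the
    temperature used to step into that day; NaN on day 0) and the four
    stage abundances.  Day 0 holds the initial state.
    """
    temps = np.asarray(temps, dtype=float)
    if params.horizon > temps.size:
        raise InputLengthError(
            f"horizon {params.horizon} exceeds temperature series length {temps.size}"
        )
    anchors = params.anchor_matrices(treatment)
    anchor_temps = [a.temperature for a in anchors]
    anchor_values = [a.values for a in anchors]

    n = params.horizon
    traj = np.empty((n + 1, 4))
    temp_col = np.full(n + 1, np.nan)
    state = np.array(params.initial_state, dtype=float)
    traj[0] = state
    for day in range(1, n + 1):
        T = temps[day - 1]
        M = _interpolate_values(anchor_temps, anchor_values, T)
        state = M @ state
        _apply_density(state, 3, params.gamma)
        np.maximum(state, 0.0, out=state)
        traj[day] = state
        temp_col[day] = T
    out = pd.DataFrame(traj, columns=list(STAGES))
    out.insert(0, "temperature", temp_col)
    out.insert(0, "day", np.arange(n + 1))
    return out


def _constant_temperature_steady_state(
    M: np.ndarray,
    gamma: float,
    initial_state: Sequence[float],
    horizon: int,
    window: int,
) -> float:
    """Mean adult density over the final ``window`` days at fixed temperature."""
    state = np.array(initial_state, dtype=float)
    acc = 0.0
    start = horizon - window
    for day in range(1, horizon + 1):
        state = M @ state
        _apply_density(state, 3, gamma)
        np.maximum(state, 0.0, out=state)
        if day > start:
            acc += state[3]
    return acc / window


def calibrate_density_dependence(
    rates: DailyRates,
    carrying_capacity: float = 500.0,
    *,
    initial_state: Sequence[float] = DEFAULT_INITIAL_STATE,
    horizon: int = 730,
    window: int = 60,
    log10_bracket: tuple[float, float] = (-9.0, 1.0),
    xtol: float = 1e-12,
) -> float:
    """Solve for ``gamma`` so the steady-state adult density equals ``K``.

    The steady state is the mean adult density over the final ``window``
    days of a ``horizon``-day run at the (constant) temperature of
    ``rates``; it decreases monotonically in ``gamma``, so the root is
    found by bisection on ``log10(gamma)``.

    Raises :class:`InfeasibleCalibrationError` when the population does
    not grow without density dependence (dominant eigenvalue <= 1).
    """
    if carrying_capacity <= 0.0:
        raise DomainError("carrying capacity must be positive")
    M = build_matrix(rates).values
    lam = np.max(np.abs(np.linalg.eigvals(M)))
    if lam <= 1.0:
        raise InfeasibleCalibrationError(
            f"population does not grow (dominant eigenvalue {lam:.4f} <= 1)"
        )

    def steady(log10_gamma: float) -> float:
        return _constant_temperature_steady_state(
            M, 10.0 ** log10_gamma, initial_state, horizon, window
        )

    lo, hi = log10_bracket
    if steady(lo) < carrying_capacity:
        raise InfeasibleCalibrationError(
            "steady state below target even at the smallest bracketed gamma"
        )
    if steady(hi) > carrying_capacity:
        raise InfeasibleCalibrationError(
            "steady state above target even at the largest bracketed gamma"
        )
    root = bisect(lambda lg: steady(lg) - carrying_capacity, lo, hi, xtol=xtol)
    return float(10.0 ** root)
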