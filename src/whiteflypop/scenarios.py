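"""Simulation experiments and summary metrics.

Runs the treatment-intensity grid (adult-, nymph- or both-stage kill
fractions from 30 to 80%), and the coverage x migration grid for the
two-patch landscape, and summarises each run by its steady-state adult
density, take-off day, delay in generations and percent reduction relative
to the untreated baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputLengthError
from .leslie import ModelParams, simulate
from .rates import TreatmentSpec
from .twopatch import MigrationSpec, simulate_two_patch

__all__ = [
    "TREATMENT_MODES",
    "DEFAULT_INTENSITIES",
    "DEFAULT_COVERAGES",
    "DEFAULT_M_MAX_VALUES",
    "ScenarioResult",
    "takeoff_day",
    "steady_state_adults",
    "percent_reduction",
    "run_treatment_grid",
    "run_coverage_grid",
]

TREATMENT_MODES = ("both", "nymph_only", "adult_only")
DEFAULT_INTENSITIES = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)  # percent
DEFAULT_COVERAGES = (0.2, 0.4, 0.6, 0.8)
DEFAULT_M_MAX_VALUES = (0.01, 0.10)


@dataclass(frozen=True)
class ScenarioResult:
    """Summary metrics of one simulated scenario.

    ``takeoff_day`` is ``None`` when the population never reaches the
    take-off threshold within the simulated horizon, in which case
    ``generations_delayed`` is NaN.
    """

    label: str
    steady_state_adults: float
    takeoff_day: int | None
    generations_delayed: float
    percent_reduction: float


def takeoff_day(
    trajectory: pd.DataFrame,
    carrying_capacity: float,
    threshold_fraction: float = 0.05,
    column: str = "adults",
) -> int | None:
    """First day the adult density reaches a fraction of carrying capacity.

    Marks the onset of population build-up; returns ``None`` when the
    threshold is never reached within the trajectory.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise DomainError("threshold fraction must lie in (0, 1)")
    threshold = threshold_fraction * carrying_capacity
    hits = np.flatnonzero(trajectory[column].to_numpy() >= threshold)
    if hits.size == 0:
        return None
    return int(trajectory["day"].iloc[hits[0]])


def steady_state_adults(
    trajectory: pd.DataFrame, window_days: int = 60, column: str = "adults"
) -> float:
    """Mean adult density over the final ``window_days`` of a trajectory."""
    if window_days < 1:
        raise DomainError("window must be at least one day")
    if len(trajectory) <= window_days:
        raise InputLengthError(
            f"trajectory of length {len(trajectory)} too short for a {window_days}-day window"
        )
    return float(trajectory[column].to_numpy()[-window_days:].mean())


def percent_reduction(wt_value: float, treated_value: float) -> float:
    """Percent reduction of a treated quantity relative to the WT baseline."""
    if wt_value <= 0.0:
        raise DomainError("baseline value must be positive")
    return 100.0 * (1.0 - treated_value / wt_value)


def _mode_treatment(mode: str, intensity_pct: float, g: float) -> TreatmentSpec:
    p = intensity_pct / 100.0
    if mode == "both":
        return TreatmentSpec(P_A=p, P_L=p, g=g)
    if mode == "nymph_only":
        return TreatmentSpec(P_A=0.0, P_L=p, g=g)
    if mode == "adult_only":
        return TreatmentSpec(P_A=p, P_L=0.0, g=g)
    raise DomainError(f"unknown treatment mode {mode!r}")


def _delay(takeoff_treated: int | None, takeoff_wt: int | None, g: float) -> float:
    if takeoff_treated is None or takeoff_wt is None:
        return math.nan
    return (takeoff_treated - takeoff_wt) / g


def run_treatment_grid(
    params: ModelParams,
    temps: Sequence[float],
    generation_days: float,
    intensities: Sequence[float] = DEFAULT_INTENSITIES,
    modes: Sequence[str] = TREATMENT_MODES,
    *,
    threshold_fraction: float = 0.05,
    window_days: int = 60,
) -> pd.DataFrame:
    """Treatment-intensity grid for a single population.

    Simulates one untreated baseline plus one run per (mode, intensity%)
    pair, with kill fractions assigned by mode (``both``: adults and
    nymphs; ``nymph_only``; ``adult_only``).  Returns one row per run with
    the summary metrics; the baseline appears once with mode ``"wt"``.
    """
    for i in intensities:
        if not 0.0 <= i <= 100.0:
            raise DomainError(f"intensity {i}% outside [0, 100]")
    K = params.carrying_capacity
    wt_traj = simulate(params, temps)
    wt_steady = steady_state_adults(wt_traj, window_days)
    wt_takeoff = takeoff_day(wt_traj, K, threshold_fraction)
    rows = [
        {
            "label": "wt", "mode": "wt", "intensity_pct": 0.0,
            "steady_state_adults": wt_steady, "takeoff_day": wt_takeoff,
            "generations_delayed": 0.0, "percent_reduction": 0.0,
        }
    ]
    for mode in modes:
        for intensity in intensities:
            treatment = _mode_treatment(mode, intensity, generation_days)
            traj = simulate(params, temps, treatment)
            steady = steady_state_adults(traj, window_days)
            toff = takeoff_day(traj, K, threshold_fraction)
            rows.append(
                {
                    "label": f"{mode}_{intensity:g}",
                    "mode": mode,
                    "intensity_pct": float(intensity),
                    "steady_state_adults": steady,
                    "takeoff_day": toff,
                    "generations_delayed": _delay(toff, wt_takeoff, generation_days),
                    "percent_reduction": percent_reduction(wt_steady, steady),
                }
            )
    return pd.DataFrame(rows)


def run_coverage_grid(
    params: ModelParams,
    temps: Sequence[float],
    generation_days: float,
    coverages: Sequence[float] = DEFAULT_COVERAGES,
    m_max_values: Sequence[float] = DEFAULT_M_MAX_VALUES,
    treatment: TreatmentSpec | None = None,
    *,
    threshold_fraction: float = 0.05,
    window_days: int = 60,
) -> pd.DataFrame:
    """Coverage x migration grid for the two-patch landscape.

    Metrics are computed for the transgenic patch.  The default treatment
    is a constant 60% reduction of both nymphal development and adult
    survival.  Reductions are relative to the single-population untreated
    baseline, which appears once with label ``"wt"``.
    """
    if treatment is None:
        treatment = TreatmentSpec(P_A=0.6, P_L=0.6, g=generation_days)
    K = params.carrying_capacity
    wt_traj = simulate(params, temps)
    wt_steady = steady_state_adults(wt_traj, window_days)
    wt_takeoff = takeoff_day(wt_traj, K, threshold_fraction)
    rows = [
        {
            "label": "wt", "coverage": math.nan, "m_max": math.nan,
            "steady_state_adults": wt_steady, "takeoff_day": wt_takeoff,
            "generations_delayed": 0.0, "percent_reduction": 0.0,
        }
    ]
    for m_max in m_max_values:
        for coverage in coverages:
            spec = MigrationSpec(m_max=m_max, coverage=coverage)
            traj = simulate_two_patch(params, temps, treatment, spec)
            steady = steady_state_adults(traj, window_days, column="tg_adults")
            toff = takeoff_day(traj, K, threshold_fraction, column="tg_adults")
            rows.append(
                {
                    "label": f"cov{coverage:g}_m{m_max:g}",
                    "coverage": float(coverage),
                    "m_max": float(m_max),
                    "steady_state_adults": steady,
                    "takeoff_day": toff,
                    "generations_delayed": _delay(toff, wt_takeoff, generation_days),
                    "percent_reduction": percent_reduction(wt_steady, steady),
                }
            )
    return pd.DataFrame(rows)
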