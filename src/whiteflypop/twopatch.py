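"""Two-patch extension: transgenic and non-transgenic plots coupled by migration.

The landscape is split into a non-transgenic (wild-type, WT) patch and a
transgenic patch.  The state vector doubles to eight components — the four
stages on WT plants followed by the four stages on transgenic plants — and
the daily projection matrix becomes 8x8 with the two single-patch matrices
on the block diagonal.  Adults migrate from WT to transgenic plants only;
the reverse flow is set to zero because WT plantings vastly exceed typical
whitefly dispersal distances.  The daily migration fraction is the maximum
rate scaled by the surrounding WT area: ``m = m_max * (1 - coverage)``,
where ``coverage`` is the fraction of the landscape planted transgenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputLengthError
from .leslie import STAGES, ModelParams, StageMatrix, _apply_density, _interpolate_values, build_matrix
from .rates import TreatmentSpec, apply_treatment

__all__ = [
    "TWO_PATCH_COLUMNS",
    "MigrationSpec",
    "effective_migration",
    "build_two_patch_matrix",
    "simulate_two_patch",
]

TWO_PATCH_COLUMNS = tuple(f"wt_{s}" for s in STAGES) + tuple(f"tg_{s}" for s in STAGES)
_WT_ADULT, _TG_ADULT = 3, 7


@dataclass(frozen=True)
class MigrationSpec:
    """Migration scenario: maximum daily adult movement and transgenic coverage."""

    m_max: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_max <= 1.0:
            raise DomainError("m_max must lie in [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise DomainError("coverage must lie in [0, 1]")


def effective_migration(spec: MigrationSpec) -> float:
    """Daily WT-to-transgenic adult migration fraction.

    Scaled by landscape composition: the more surrounding WT area (lower
    transgenic coverage), the more adult immigration a transgenic plot
    receives; at full coverage there are no WT neighbours and migration
    vanishes.
    """
    return spec.m_max * (1.0 - spec.coverage)


def build_two_patch_matrix(
    M_wt: StageMatrix, M_tg: StageMatrix, m: float
) -> np.ndarray:
    """Couple two single-patch matrices with adult migration fraction ``m``.

    A fraction ``m`` of WT adults moves to the transgenic patch each day
    before experiencing that day's survival, so the within-patch WT adult
    entry is multiplied by ``(1 - m)`` and the coupling entry (transgenic
    adult row, WT adult column) is ``m`` times the WT adult daily
    survival.  No entry ever routes transgenic insects back to the WT
    patch.  Migration itself neither creates nor destroys adults: summed
    over patches the pre-survival flow is conserved.
    """
    if not 0.0 <= m <= 1.0:
        raise DomainError("migration fraction must lie in [0, 1]")
    B = np.zeros((8, 8))
    B[:4, :4] = M_wt.values
    B[4:, 4:] = M_tg.values
    wt_adult_survival = M_wt.values[3, 3]
    B[_WT_ADULT, _WT_ADULT] = (1.0 - m) * wt_adult_survival
    B[_TG_ADULT, _WT_ADULT] = m * wt_adult_survival
    return B


def simulate_two_patch(
    params: ModelParams,
    temps: Sequence[float],
    treatment: TreatmentSpec | None,
    spec: MigrationSpec,
    *,
    initial_state: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate the coupled WT/transgenic system.

    The WT patch uses untreated matrices, the transgenic patch treated
    ones; density-dependent adult mortality (same ``gamma``) acts within
    each patch separately.  By default both patches start from the
    single-patch initial state.  Returns a DataFrame with ``day``,
    ``temperature`` and the eight ``wt_*`` / ``tg_*`` abundance columns.
    """
    temps = np.asarray(temps, dtype=float)
    if params.horizon > temps.size:
        raise InputLengthError(
            f"horizon {params.horizon} exceeds temperature series length {temps.size}"
        )
    m = effective_migration(spec)
    wt_rates = params.anchor_rates
    tg_rates = (
        tuple(apply_treatment(r, treatment) for r in wt_rates)
        if treatment is not None
        else wt_rates
    )
    anchor_temps = [r.temperature for r in wt_rates]
    anchor_values = [
        build_two_patch_matrix(build_matrix(wt), build_matrix(tg), m)
        for wt, tg in zip(wt_rates, tg_rates)
    ]

    if initial_state is None:
        state = np.array(params.initial_state * 2, dtype=float)
    else:
        state = np.asarray(initial_state, dtype=float).copy()
        if state.shape != (8,):
            raise DomainError("two-patch initial state must have eight components")
        if np.any(state < 0.0):
            raise DomainError("initial abundances must be non-negative")

    n = params.horizon
    traj = np.empty((n + 1, 8))
    temp_col = np.full(n + 1, np.nan)
    traj[0] = state
    for day in range(1, n + 1):
        T = temps[day - 1]
        B = _interpolate_values(anchor_temps, anchor_values, T)
        state = B @ state
        _apply_density(state, _WT_ADULT, params.gamma)
        _apply_density(state, _TG_ADULT, params.gamma)
        np.maximum(state, 0.0, out=state)
        traj[day] = state
        temp_col[day] = T
    out = pd.DataFrame(traj, columns=list(TWO_PATCH_COLUMNS))
    out.insert(0, "temperature", temp_col)
    out.insert(0, "day", np.arange(n + 1))
    return out
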