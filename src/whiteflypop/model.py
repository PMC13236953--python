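"""Model/Results front end for the whitefly population dynamics pipeline.

:class:`WhiteflyPopulationModel` bundles the raw inputs (life tables at
the anchor temperatures, a daily temperature series, calibration targets).
Its :meth:`~WhiteflyPopulationModel.fit` performs the two calibrations the
analysis rests on — the field-mortality adjustment ``q`` (matching ~10%
egg-to-adult emergence) and the density-dependence coefficient ``gamma``
(matching a carrying capacity of ~500 adults per leaf) — and returns a
:class:`WhiteflyPopulationResults` that carries the estimates and exposes
simulation, scenario grids and plotting.

Example
-------
>>> from whiteflypop import WhiteflyPopulationModel
>>> res = WhiteflyPopulationModel.from_synthetic(seed=1).fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> traj = res.simulate(treatment=res.treatment(P_A=0.6, P_L=0.6))
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .leslie import (
    DEFAULT_INITIAL_STATE,
    ModelParams,
    calibrate_density_dependence,
    simulate,
)
from .rates import (
    DailyRates,
    LifeTable,
    TreatmentSpec,
    calibrate_field_adjustment,
    emergence_probability,
    generation_time,
    life_table_to_daily_rates,
    with_field_adjustment,
)
from .scenarios import (
    DEFAULT_COVERAGES,
    DEFAULT_INTENSITIES,
    DEFAULT_M_MAX_VALUES,
    TREATMENT_MODES,
    run_coverage_grid,
    run_treatment_grid,
)
from .twopatch import MigrationSpec, simulate_two_patch

__all__ = ["WhiteflyPopulationModel", "WhiteflyPopulationResults"]


class WhiteflyPopulationModel:
    """Temperature-driven stage-structured model of *Bemisia tabaci* dynamics.

    Parameters
    ----------
    life_tables : mapping of temperature -> LifeTable, or iterable of LifeTable
        Laboratory vital rates at the anchor temperatures.
    temperatures : sequence of float
        Daily mean temperatures (degC) driving the simulation.
    target_emergence : float, default 0.10
        Observed field egg-to-adult emergence fraction the field-mortality
        adjustment ``q`` is calibrated against.
    carrying_capacity : float, default 500
        Steady-state adult density per leaf the density-dependence
        coefficient ``gamma`` is calibrated against.
    reference_temperature : float, default 28
        Anchor at which ``q``, ``gamma`` and the generation length are
        calibrated (must be one of the anchor temperatures).
    initial_state : 4-tuple, default (0, 0, 0, 1)
        Initial (eggs, nymphs, pupae, adults) per leaf.
    horizon : int, default 730
        Simulation length in days (must not exceed the temperature series).
    """

    def __init__(
        self,
        life_tables: Mapping[float, LifeTable] | Iterable[LifeTable],
        temperatures: Sequence[float],
        *,
        target_emergence: float = 0.10,
        carrying_capacity: float = 500.0,
        reference_temperature: float = 28.0,
        initial_state: Sequence[float] = DEFAULT_INITIAL_STATE,
        horizon: int = 730,
    ) -> None:
        if isinstance(life_tables, Mapping):
            tables = list(life_tables.values())
        else:
            tables = list(life_tables)
        if len(tables) < 2:
            raise ConfigurationError("need life tables at >= 2 anchor temperatures")
        tables.sort(key=lambda t: t.temperature)
        self.life_tables: tuple[LifeTable, ...] = tuple(tables)
        self.anchor_temps: tuple[float, ...] = tuple(t.temperature for t in tables)
        if reference_temperature not in self.anchor_temps:
            raise ConfigurationError(
                f"reference temperature {reference_temperature} is not an anchor "
                f"{self.anchor_temps}"
            )
        self.temperatures = np.asarray(temperatures, dtype=float)
        if horizon > self.temperatures.size:
            raise ConfigurationError("horizon exceeds the temperature series length")
        self.target_emergence = float(target_emergence)
        self.carrying_capacity = float(carrying_capacity)
        self.reference_temperature = float(reference_temperature)
        self.initial_state = tuple(float(x) for x in initial_state)
        self.horizon = int(horizon)

    @classmethod
    def from_synthetic(cls, seed: int = 1, config=None, **kwargs) -> "WhiteflyPopulationModel":
        """Build the model from the synthetic default fixture."""
        from .synthetic import SyntheticConfig, generate_life_tables, generate_temperature_series

        config = config or SyntheticConfig(seed=seed)
        return cls(
            generate_life_tables(config),
            generate_temperature_series(config),
            **kwargs,
        )

    @classmethod
    def from_csv(
        cls, life_tables_csv: str | Path, temperatures_csv: str | Path, **kwargs
    ) -> "WhiteflyPopulationModel":
        """Build the model from the delimited-text input files."""
        from .synthetic import read_life_tables_csv, read_temperature_csv

        return cls(
            read_life_tables_csv(life_tables_csv),
            read_temperature_csv(temperatures_csv),
            **kwargs,
        )

    def fit(self) -> "WhiteflyPopulationResults":
        """Calibrate ``q`` and ``gamma`` and return the fitted results."""
        base_rates = {t.temperature: life_table_to_daily_rates(t) for t in self.life_tables}
        ref = base_rates[self.reference_temperature]
        q = calibrate_field_adjustment(ref, self.target_emergence)
        adjusted = tuple(
            with_field_adjustment(base_rates[T], q) for T in self.anchor_temps
        )
        ref_adjusted = adjusted[self.anchor_temps.index(self.reference_temperature)]
        g = generation_time(ref_adjusted)
        gamma = calibrate_density_dependence(
            ref_adjusted,
            self.carrying_capacity,
            initial_state=self.initial_state,
            horizon=max(self.horizon, 730),
        )
        params = ModelParams(
            anchor_rates=adjusted,
            gamma=gamma,
            carrying_capacity=self.carrying_capacity,
            initial_state=self.initial_state,
            horizon=self.horizon,
        )
        return WhiteflyPopulationResults(
            model=self,
            q=q,
            gamma=gamma,
            generation_days=g,
            emergence=emergence_probability(ref_adjusted),
            params=params,
        )


class WhiteflyPopulationResults:
    """Fitted whitefly population model.

    Attributes
    ----------
    q_ : float
        Calibrated additive daily field mortality of immature stages.
    gamma_ : float
        Calibrated density-dependence coefficient (per adults-per-leaf per day).
    generation_days_ : int
        Egg-to-adult generation length at the reference temperature.
    emergence_ : float
        Post-calibration egg-to-adult emergence probability.
    params_ : ModelParams
        Field-adjusted anchor rates plus ``gamma``, ready to simulate.
    """

    def __init__(self, model, q, gamma, generation_days, emergence, params) -> None:
        self.model = model
        self.q_ = float(q)
        self.gamma_ = float(gamma)
        self.generation_days_ = int(generation_days)
        self.emergence_ = float(emergence)
        self.params_ = params

    # -- parameter access ---------------------------------------------------

    def treatment(self, P_A: float, P_L: float) -> TreatmentSpec:
        """A treatment specification using the fitted generation length."""
        return TreatmentSpec(P_A=P_A, P_L=P_L, g=self.generation_days_)

    def anchor_rates(self) -> tuple[DailyRates, ...]:
        return self.params_.anchor_rates

    # -- simulation ---------------------------------------------------------

    def simulate(
        self,
        treatment: TreatmentSpec | None = None,
        temps: Sequence[float] | None = None,
        horizon: int | None = None,
    ) -> pd.DataFrame:
        """Daily single-population trajectory under the fitted parameters."""
        params = self.params_
        if horizon is not None:
            import dataclasses

            params = dataclasses.replace(params, horizon=int(horizon))
        return simulate(params, self.model.temperatures if temps is None else temps, treatment)

    def simulate_two_patch(
        self,
        migration: MigrationSpec,
        treatment: TreatmentSpec | None = None,
        temps: Sequence[float] | None = None,
    ) -> pd.DataFrame:
        """Coupled WT/transgenic trajectory under the fitted parameters."""
        return simulate_two_patch(
            self.params_,
            self.model.temperatures if temps is None else temps,
            treatment,
            migration,
        )

    # -- scenario grids -----------------------------------------------------

    def treatment_grid(
        self,
        intensities: Sequence[float] = DEFAULT_INTENSITIES,
        modes: Sequence[str] = TREATMENT_MODES,
        temps: Sequence[float] | None = None,
        **kwargs,
    ) -> pd.DataFrame:
        """Treatment-intensity grid (see :func:`scenarios.run_treatment_grid`)."""
        return run_treatment_grid(
            self.params_,
            self.model.temperatures if temps is None else temps,
            self.generation_days_,
            intensities,
            modes,
            **kwargs,
        )

    def coverage_grid(
        self,
        coverages: Sequence[float] = DEFAULT_COVERAGES,
        m_max_values: Sequence[float] = DEFAULT_M_MAX_VALUES,
        treatment: TreatmentSpec | None = None,
        temps: Sequence[float] | None = None,
        **kwargs,
    ) -> pd.DataFrame:
        """Coverage x migration grid (see :func:`scenarios.run_coverage_grid`)."""
        return run_coverage_grid(
            self.params_,
            self.model.temperatures if temps is None else temps,
            self.generation_days_,
            coverages,
            m_max_values,
            treatment,
            **kwargs,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        m = self.model
        anchors = ", ".join(f"{t:g}" for t in m.anchor_temps)
        lines = [
            "        Whitefly population dynamics model",
            "=" * 56,
            f"Stages:                  egg, nymph, pupa, adult (daily)",
            f"Anchor temperatures:     {anchors} degC",
            f"Temperature series:      {m.temperatures.size} days "
            f"(mean {m.temperatures.mean():.1f} degC)",
            f"Reference temperature:   {m.reference_temperature:g} degC",
            f"Simulation horizon:      {m.horizon} days",
            "-" * 56,
            f"q (field mortality)      {self.q_:.6f}  per day (egg/nymph/pupa)",
            f"gamma (density dep.)     {self.gamma_:.6e}  per (adults/leaf)/day",
            f"Emergence (calibrated)   {self.emergence_ * 100:.2f} %  "
            f"(target {m.target_emergence * 100:g} %)",
            f"Generation length g      {self.generation_days_} days",
            f"Carrying capacity K      {m.carrying_capacity:g} adults/leaf (target)",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<WhiteflyPopulationResults q={self.q_:.4f} gamma={self.gamma_:.3e} "
            f"g={self.generation_days_}d emergence={self.emergence_:.3f}>"
        )

    # -- plotting -----------------------------------------------------------

    def plot_adults(
        self,
        trajectories: Mapping[str, pd.DataFrame] | pd.DataFrame,
        column: str = "adults",
        ax=None,
    ):
        """Plot adult density over time for one or more trajectories.

        ``trajectories`` is either a single trajectory DataFrame or a
        mapping of label -> trajectory.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4.5))
        if isinstance(trajectories, pd.DataFrame):
            trajectories = {"adults": trajectories}
        for label, traj in trajectories.items():
            ax.plot(traj["day"], traj[column], label=label)
        ax.set_xlabel("day")
        ax.set_ylabel("adults per leaf")
        ax.axhline(self.model.carrying_capacity, ls=":", c="grey", lw=0.8)
        if len(trajectories) > 1:
            ax.legend(fontsize=8)
        return ax
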