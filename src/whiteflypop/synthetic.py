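"""Synthetic inputs: life tables, temperature series, sequence panels.

The pipeline's real inputs are laboratory life tables of *Bemisia tabaci*
at five anchor temperatures, a Kampala (Uganda) daily mean-temperature
series, and FASTA files of candidate dsRNAs and reference genomes.  This
module generates stand-ins with the statistical structure the analysis
assumes, so the pipeline and its tests never need an external download.

Vital-rate shapes
-----------------
Stage-level whitefly demography is smooth and unimodal in temperature
within the 16-32 degC band, with development fastest and fecundity highest
at warm-intermediate temperatures.  The generator uses quadratic curves
centred at 28 degC:

* median stage durations scale as ``1 + 0.005 (T - 28)^2`` about base
  durations of 4 d (egg), 3+3+3+3 d (nymph instars) and 4 d (pupa), giving
  an egg-to-adult generation time of ~20 days at 28 degC;
* stage survivals drop quadratically from their 28 degC values (egg and
  pupa 0.70, nymph instars 0.995, adult daily survival 0.95) by
  ``0.0005 (T - 28)^2``; laboratory losses are concentrated in the egg and
  pupal stages (moulting failures) with low per-instar nymph mortality, so
  the field adjustment ``q`` — not the laboratory baseline — dominates
  immature field mortality;
* fecundity is ``8 (1 - ((T - 28)/20)^2)`` eggs per adult per day, within
  the published range for *B. tabaci* on suitable hosts.

A small seeded log-normal jitter (sigma = 1%) on durations and fecundity
and additive noise (sigma = 0.003) on survivals make replicate tables
distinguishable without disturbing the qualitative structure.  All
constants are module-level and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .offtarget import reverse_complement
from .rates import LifeTable

__all__ = [
    "SyntheticConfig",
    "generate_life_tables",
    "generate_temperature_series",
    "generate_sequence_panel",
    "write_life_tables_csv",
    "read_life_tables_csv",
    "write_temperature_csv",
    "read_temperature_csv",
]

DEFAULT_ANCHOR_TEMPS = (16.0, 20.0, 24.0, 28.0, 32.0)

# fixture constants (28 degC references; see the methods note)
T_OPT = 28.0
BASE_M_EGG = 4.0
BASE_NYMPH_DURATIONS = (3.0, 3.0, 3.0, 3.0)
BASE_M_PUPA = 4.0
DURATION_CURVATURE = 0.005          # per degC^2, multiplicative
BASE_EGG_SURVIVAL = 0.70
BASE_NYMPH_SURVIVAL = 0.995
BASE_PUPA_SURVIVAL = 0.70
BASE_ADULT_DAILY_SURVIVAL = 0.95
SURVIVAL_CURVATURE = 0.0005         # per degC^2, subtractive
BASE_FECUNDITY = 8.0                # eggs per adult per day at 28 degC
FECUNDITY_WIDTH = 20.0              # degC half-width of the fecundity parabola
DURATION_JITTER_SD = 0.01           # log-normal sigma
SURVIVAL_JITTER_SD = 0.003          # additive sigma
_SURVIVAL_FLOOR, _SURVIVAL_CEIL = 0.05, 0.999


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic generators.

    Defaults emulate the study conditions: five anchor temperatures
    16-32 degC and a near-constant tropical (Kampala-like) temperature
    series, mean 23 degC with a 4 degC seasonal amplitude and 1 degC daily
    noise, clamped to the anchor range.
    """

    seed: int = 1
    n_days: int = 730
    temp_mean: float = 23.0
    temp_amplitude: float = 4.0
    temp_noise_sd: float = 1.0
    anchor_temps: tuple[float, ...] = DEFAULT_ANCHOR_TEMPS

    def __post_init__(self) -> None:
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        object.__setattr__(self, "anchor_temps", tuple(float(t) for t in self.anchor_temps))
        if len(self.anchor_temps) < 2:
            raise ConfigurationError("need at least two anchor temperatures")
        if sorted(self.anchor_temps) != list(self.anchor_temps):
            raise ConfigurationError("anchor temperatures must be sorted ascending")
        if self.temp_noise_sd < 0 or self.temp_amplitude < 0:
            raise ConfigurationError("temperature amplitude and noise must be non-negative")


def _duration_factor(T: float) -> float:
    return 1.0 + DURATION_CURVATURE * (T - T_OPT) ** 2


def _survival(base: float, T: float) -> float:
    return float(np.clip(base - SURVIVAL_CURVATURE * (T - T_OPT) ** 2,
                         _SURVIVAL_FLOOR, _SURVIVAL_CEIL))


def _fecundity(T: float) -> float:
    return max(0.0, BASE_FECUNDITY * (1.0 - ((T - T_OPT) / FECUNDITY_WIDTH) ** 2))


def generate_life_tables(config: SyntheticConfig | None = None) -> dict[float, LifeTable]:
    """One synthetic life table per anchor temperature, keyed by temperature.

    Identical configs produce identical tables.  Durations are >= 1 day,
    survivals in (0, 1], and development is fastest / fecundity highest at
    the warm-intermediate anchors.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    tables: dict[float, LifeTable] = {}
    for T in config.anchor_temps:
        f = _duration_factor(T)
        jit = lambda: float(np.exp(rng.normal(0.0, DURATION_JITTER_SD)))
        sjit = lambda base: float(
            np.clip(_survival(base, T) + rng.normal(0.0, SURVIVAL_JITTER_SD),
                    _SURVIVAL_FLOOR, _SURVIVAL_CEIL)
        )
        tables[T] = LifeTable(
            temperature=T,
            m_egg=max(1.0, BASE_M_EGG * f * jit()),
            m_pupa=max(1.0, BASE_M_PUPA * f * jit()),
            nymph_durations=tuple(max(1.0, t * f * jit()) for t in BASE_NYMPH_DURATIONS),
            egg_survival=sjit(BASE_EGG_SURVIVAL),
            nymph_survivals=tuple(sjit(BASE_NYMPH_SURVIVAL) for _ in range(4)),
            pupa_survival=sjit(BASE_PUPA_SURVIVAL),
            adult_daily_survival=sjit(BASE_ADULT_DAILY_SURVIVAL),
            fecundity=_fecundity(T) * jit(),
        )
    return tables


def generate_temperature_series(config: SyntheticConfig | None = None) -> np.ndarray:
    """Daily mean temperatures: sinusoidal seasonal term plus Gaussian noise.

    Values are clamped to the anchor range so every simulated day lies
    within the parameterized band.  Deterministic for a fixed config.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from the life-table stream
    days = np.arange(config.n_days)
    series = (
        config.temp_mean
        + config.temp_amplitude * np.sin(2.0 * np.pi * days / 365.0)
        + rng.normal(0.0, config.temp_noise_sd, size=config.n_days)
    )
    return np.clip(series, config.anchor_temps[0], config.anchor_temps[-1])


def generate_sequence_panel(
    seed: int = 1,
    n_refs: int = 3,
    ref_length: int = 2000,
    planted: Sequence[tuple] = (),
    *,
    n_dsrna: int = 2,
    dsrna_length: int = 200,
    k: int = 21,
    ref_alphabet: str = "ACGT",
    dsrna_alphabet: str = "ACGT",
) -> tuple[dict[str, str], dict[str, str]]:
    """Random dsRNA and reference sequences with optional planted matches.

    ``planted`` entries are ``(dsrna_id, ref_id, strand, position)`` tuples
    (optionally with a fifth element, the 0-based k-mer offset within the
    dsRNA, default 0): the dsRNA's k-mer is copied — reverse-complemented
    for strand ``"-"`` — into the reference at the stated 0-based position.
    Returns ``(dsrnas, references)`` as id -> sequence mappings.
    """
    if n_refs < 1 or n_dsrna < 1:
        raise ConfigurationError("need at least one reference and one dsRNA")
    if ref_length < 1 or dsrna_length < 1:
        raise ConfigurationError("sequence lengths must be positive")
    rng = np.random.default_rng(seed)

    def draw(length: int, alphabet: str) -> str:
        letters = np.array(list(alphabet))
        return "".join(letters[rng.integers(0, len(letters), size=length)])

    dsrnas = {f"dsrna-{i + 1}": draw(dsrna_length, dsrna_alphabet) for i in range(n_dsrna)}
    refs = {f"ref-{i + 1}": draw(ref_length, ref_alphabet) for i in range(n_refs)}

    for entry in planted:
        ds_id, ref_id, strand, position, *rest = entry
        offset = int(rest[0]) if rest else 0
        if ds_id not in dsrnas or ref_id not in refs:
            raise ConfigurationError(f"unknown id in planted entry {entry!r}")
        if strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be '+' or '-', got {strand!r}")
        seq = dsrnas[ds_id]
        if len(seq) < k:
            raise DomainError(f"{ds_id} shorter than {k} nt; cannot plant a k-mer")
        if not 0 <= offset <= len(seq) - k:
            raise DomainError(f"k-mer offset {offset} out of range for {ds_id}")
        if not 0 <= position <= ref_length - k:
            raise DomainError(f"planting position {position} does not fit in {ref_id}")
        insert = seq[offset : offset + k]
        if strand == "-":
            insert = reverse_complement(insert)
        ref = refs[ref_id]
        refs[ref_id] = ref[:position] + insert + ref[position + k :]
    return dsrnas, refs


# ---------------------------------------------------------------------------
# delimited-text schemas

_LIFETABLE_COLUMNS = ("temperature_C", "stage", "median_days", "survival", "fecundity_per_day")
_STAGE_ROWS = ("egg", "nymph1", "nymph2", "nymph3", "nymph4", "pupa", "adult")


def write_life_tables_csv(tables: Mapping[float, LifeTable], path: str | Path) -> None:
    """Write life tables as CSV, one row per (temperature, stage).

    The ``adult`` row stores the daily adult survival in ``survival`` and
    the fecundity in ``fecundity_per_day``; its ``median_days`` is empty.
    """
    rows = []
    for T in sorted(tables):
        t = tables[T]
        rows.append((T, "egg", t.m_egg, t.egg_survival, np.nan))
        for j in range(4):
            rows.append((T, f"nymph{j + 1}", t.nymph_durations[j], t.nymph_survivals[j], np.nan))
        rows.append((T, "pupa", t.m_pupa, t.pupa_survival, np.nan))
        rows.append((T, "adult", np.nan, t.adult_daily_survival, t.fecundity))
    pd.DataFrame(rows, columns=list(_LIFETABLE_COLUMNS)).to_csv(path, index=False)


def read_life_tables_csv(path: str | Path) -> dict[float, LifeTable]:
    """Read life tables written by :func:`write_life_tables_csv`."""
    df = pd.read_csv(path)
    missing = set(_LIFETABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"life-table CSV missing columns {sorted(missing)}")
    tables: dict[float, LifeTable] = {}
    for T, grp in df.groupby("temperature_C"):
        g = grp.set_index("stage")
        if set(_STAGE_ROWS) - set(g.index):
            raise ConfigurationError(f"temperature {T}: incomplete stage rows")
        tables[float(T)] = LifeTable(
            temperature=float(T),
            m_egg=float(g.loc["egg", "median_days"]),
            m_pupa=float(g.loc["pupa", "median_days"]),
            nymph_durations=tuple(
                float(g.loc[f"nymph{j + 1}", "median_days"]) for j in range(4)
            ),
            egg_survival=float(g.loc["egg", "survival"]),
            nymph_survivals=tuple(
                float(g.loc[f"nymph{j + 1}", "survival"]) for j in range(4)
            ),
            pupa_survival=float(g.loc["pupa", "survival"]),
            adult_daily_survival=float(g.loc["adult", "survival"]),
            fecundity=float(g.loc["adult", "fecundity_per_day"]),
        )
    return tables


def write_temperature_csv(series: Sequence[float], path: str | Path) -> None:
    """Write a daily temperature series as CSV with day index and degC."""
    pd.DataFrame(
        {"day": np.arange(len(series)), "temperature_C": np.asarray(series, dtype=float)}
    ).to_csv(path, index=False)


def read_temperature_csv(path: str | Path) -> np.ndarray:
    """Read a temperature series written by :func:`write_temperature_csv`."""
    df = pd.read_csv(path)
    if "temperature_C" not in df.columns:
        raise ConfigurationError("temperature CSV missing 'temperature_C' column")
    return df["temperature_C"].to_numpy(dtype=float)
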