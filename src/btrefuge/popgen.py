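"""Deterministic one-locus, two-allele model of Bt-resistance evolution.

The model tracks the frequency ``p`` of a resistance allele (``r``; here the
T92C substitution in *HaTSPAN1* conferring dominant resistance of
*Helicoverpa armigera* to Cry1Ac) in a single panmictic population whose
habitat is a mixture of Bt cotton and non-Bt refuge host plants.  Each
generation, genotypes form by random mating (Hardy-Weinberg proportions),
are selected with habitat-weighted marginal fitness, and adults mate at
random across habitats.  Three generations per year correspond to the
bollworm's three generations on cotton in northern China.

Genotype fitness is parameterised by

* ``h`` — dominance of resistance on Bt cotton (0 recessive, 1 dominant),
* ``cost`` — recessive fitness cost of ``rr`` on non-Bt host plants,
* ``incomplete_resistance`` — fitness of ``rr`` on Bt cotton (resistant
  insects do worse on Bt cotton than on non-Bt hosts),
* ``w_ss_bt`` — fitness of susceptible homozygotes on Bt cotton
  (0 under full efficacy: diagnostic-dose mortality of susceptibles is 100%).

With refuge fraction ``R`` the marginal fitness of genotype ``g`` is the
mixture ``R * w_g_refuge + (1 - R) * w_g_bt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "FitnessTable",
    "RefugeSeries",
    "ScenarioConfig",
    "Trajectory",
    "ExtinctionError",
    "build_fitness_table",
    "habitat_fitness",
    "advance_generation",
    "simulate_trajectory",
    "overdominance_equilibrium",
    "run_scenarios",
]

#: Empirical defaults for the T92C / Cry1Ac system in northern China.
DEFAULT_H = 0.79
DEFAULT_COST = 0.36
DEFAULT_INCOMPLETE_RESISTANCE = 0.49
DEFAULT_W_SS_BT = 0.0
DEFAULT_P0 = 0.001
GENERATIONS_PER_YEAR = 3


class ExtinctionError(ValueError):
    """Mean fitness is zero: no genotype survives, the recursion is undefined."""


def _check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class FitnessTable:
    """Relative fitness of ss/rs/rr genotypes on Bt cotton and in refuge.

    All values are relative to susceptible homozygotes on non-Bt hosts
    (``w_ss_ref`` is fixed at 1).
    """

    w_ss_bt: float
    w_rs_bt: float
    w_rr_bt: float
    w_ss_ref: float = 1.0
    w_rs_ref: float = 1.0
    w_rr_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_ss_bt", "w_rs_bt", "w_rr_bt", "w_ss_ref", "w_rs_ref", "w_rr_ref"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.w_ss_ref != 1.0:
            raise ValueError("fitness is normalised to w_ss_ref = 1")

    @property
    def bt(self) -> tuple[float, float, float]:
        return (self.w_ss_bt, self.w_rs_bt, self.w_rr_bt)

    @property
    def refuge(self) -> tuple[float, float, float]:
        return (self.w_ss_ref, self.w_rs_ref, self.w_rr_ref)


def build_fitness_table(
    h: float = DEFAULT_H,
    cost: float = DEFAULT_COST,
    incomplete_resistance: float = DEFAULT_INCOMPLETE_RESISTANCE,
    w_ss_bt: float = DEFAULT_W_SS_BT,
    incomplete_resistance_mode: str = "absolute",
) -> FitnessTable:
    """Compose the genotype fitness table from the four scalar parameters.

    On non-Bt hosts the cost is recessive: ``w_rs_ref = 1`` and
    ``w_rr_ref = 1 - cost``.  On Bt cotton the heterozygote sits at fraction
    ``h`` between the homozygotes, ``w_rs_bt = w_ss_bt + h * (w_rr_bt - w_ss_bt)``.

    ``incomplete_resistance_mode`` selects how the incomplete-resistance
    parameter enters:

    ``"absolute"`` (default)
        ``w_rr_bt = incomplete_resistance`` — the measured fitness of
        resistant homozygotes on Bt cotton itself (0.49, lower than their
        0.64 on non-Bt hosts).
    ``"ratio"``
        ``w_rr_bt = incomplete_resistance * (1 - cost)`` — incomplete
        resistance read as a Bt/non-Bt fitness ratio for ``rr``.
    """
    h = _check_unit_interval("h", h)
    cost = _check_unit_interval("cost", cost)
    incomplete_resistance = _check_unit_interval("incomplete_resistance", incomplete_resistance)
    w_ss_bt = _check_unit_interval("w_ss_bt", w_ss_bt)

    w_rr_ref = 1.0 - cost
    if incomplete_resistance_mode == "absolute":
        w_rr_bt = incomplete_resistance
    elif incomplete_resistance_mode == "ratio":
        w_rr_bt = incomplete_resistance * w_rr_ref
    else:
        raise ValueError(
            "incomplete_resistance_mode must be 'absolute' or 'ratio', "
            f"got {incomplete_resistance_mode!r}"
        )
    w_rs_bt = w_ss_bt + h * (w_rr_bt - w_ss_bt)
    return FitnessTable(
        w_ss_bt=w_ss_bt,
        w_rs_bt=w_rs_bt,
        w_rr_bt=w_rr_bt,
        w_rs_ref=1.0,
        w_rr_ref=w_rr_ref,
    )


def habitat_fitness(
    table: FitnessTable, refuge_fraction: float
) -> tuple[float, float, float]:
    """Marginal (habitat-weighted) genotype fitness at refuge fraction ``R``.

    Under random oviposition across habitats and random mating of the
    emerging adults, genotype ``g`` experiences
    ``w_g = R * w_g_refuge + (1 - R) * w_g_bt``.
    """
    R = _check_unit_interval("refuge_fraction", refuge_fraction)
    return tuple(
        R * wr + (1.0 - R) * wb for wr, wb in zip(table.refuge, table.bt)
    )  # type: ignore[return-value]


def advance_generation(p: float, w: tuple[float, float, float]) -> float:
    """One generation of the Hardy-Weinberg selection recursion.

    ``p' = p (p w_rr + q w_rs) / (p^2 w_rr + 2 p q w_rs + q^2 w_ss)`` with
    ``q = 1 - p`` and ``w = (w_ss, w_rs, w_rr)``.
    """
    p = _check_unit_interval("p", p)
    w_ss, w_rs, w_rr = w
    q = 1.0 - p
    mean_w = p * p * w_rr + 2.0 * p * q * w_rs + q * q * w_ss
    if mean_w <= 0.0:
        raise ExtinctionError(
            f"mean fitness is {mean_w} at p={p}: population extinct"
        )
    p_next = p * (p * w_rr + q * w_rs) / mean_w
    # guard the exact boundary against rounding
    return min(1.0, max(0.0, p_next))


def overdominance_equilibrium(
    w: tuple[float, float, float]
) -> Optional[float]:
    """Stable polymorphic equilibrium under heterozygote advantage, if any.

    If ``w_rs > max(w_ss, w_rr)`` the recursion converges to the classical
    balanced polymorphism ``p* = (w_rs - w_ss) / (2 w_rs - w_ss - w_rr)``;
    otherwise returns ``None``.
    """
    w_ss, w_rs, w_rr = w
    if w_rs > w_ss and w_rs > w_rr:
        return (w_rs - w_ss) / (2.0 * w_rs - w_ss - w_rr)
    return None


@dataclass(frozen=True)
class RefugeSeries:
    """Yearly refuge fraction (dimensionless share of selection habitat)."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        for year, r in self.values.items():
            _check_unit_interval(f"refuge fraction for {year}", r)

    @classmethod
    def constant(cls, r: float, years: Iterable[int]) -> "RefugeSeries":
        return cls({int(y): float(r) for y in years})

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(
                f"no refuge fraction configured for year {year}"
            ) from None

    def __contains__(self, year: int) -> bool:
        return year in self.values

    def years(self) -> list[int]:
        return sorted(self.values)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: time span, initial frequency, fitness, refuge.

    The trajectory reports the allele frequency for each calendar year after
    that year's ``generations_per_year`` rounds of selection under that
    year's refuge fraction; ``p0`` is the (observed) frequency anchored at
    ``start_year``.  The refuge series must therefore cover
    ``start_year + 1 .. end_year``.
    """

    start_year: int
    end_year: int
    refuge_series: RefugeSeries
    p0: float = DEFAULT_P0
    generations_per_year: int = GENERATIONS_PER_YEAR
    h: float = DEFAULT_H
    cost: float = DEFAULT_COST
    incomplete_resistance: float = DEFAULT_INCOMPLETE_RESISTANCE
    w_ss_bt: float = DEFAULT_W_SS_BT
    incomplete_resistance_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        _check_unit_interval("p0", self.p0)
        if self.generations_per_year < 1:
            raise ValueError("generations_per_year must be >= 1")

    def fitness_table(self) -> FitnessTable:
        return build_fitness_table(
            h=self.h,
            cost=self.cost,
            incomplete_resistance=self.incomplete_resistance,
            w_ss_bt=self.w_ss_bt,
            incomplete_resistance_mode=self.incomplete_resistance_mode,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        refuge = d.pop("refuge")
        if isinstance(refuge, (int, float)):
            series = RefugeSeries.constant(
                refuge, range(int(d["start_year"]), int(d["end_year"]) + 1)
            )
        else:
            series = RefugeSeries({int(y): float(r) for y, r in refuge.items()})
        return cls(refuge_series=series, **d)


@dataclass(frozen=True)
class Trajectory:
    """Yearly resistance-allele frequency path produced by one scenario."""

    frequencies: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", dict(self.frequencies))

    def __getitem__(self, year: int) -> float:
        return self.frequencies[year]

    def years(self) -> list[int]:
        return sorted(self.frequencies)

    def first_year_exceeding(self, threshold: float) -> Optional[int]:
        for year in self.years():
            if self.frequencies[year] > threshold:
                return year
        return None

    def to_frame(self, name: str = "p") -> pd.DataFrame:
        years = self.years()
        return pd.DataFrame({"year": years, name: [self.frequencies[y] for y in years]})


def simulate_trajectory(config: ScenarioConfig) -> Trajectory:
    """Run the yearly selection recursion for one scenario.

    The frequency recorded for ``start_year`` is ``p0``; for each later year
    ``y`` it is the frequency after ``generations_per_year`` generations of
    selection at the habitat-weighted fitness for refuge fraction ``R(y)``.
    """
    table = config.fitness_table()
    for year in range(config.start_year + 1, config.end_year + 1):
        if year not in config.refuge_series:
            raise KeyError(
                f"refuge series does not cover simulated year {year}"
            )
    p = config.p0
    freqs = {config.start_year: p}
    for year in range(config.start_year + 1, config.end_year + 1):
        w = habitat_fitness(table, config.refuge_series[year])
        for _ in range(config.generations_per_year):
            p = advance_generation(p, w)
        freqs[year] = p
    return Trajectory(freqs)


def run_scenarios(
    configs: Mapping[str, ScenarioConfig],
    observed: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Simulate a named set of scenarios into one tidy table.

    Returns a DataFrame with columns ``scenario, year, p`` (and ``observed``
    where a matching year is supplied).  Deterministic: identical inputs give
    identical tables.
    """
    if not configs:
        raise ValueError("at least one scenario is required")
    frames = []
    for name, config in configs.items():
        frame = simulate_trajectory(config).to_frame()
        frame.insert(0, "scenario", name)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if observed is not None:
        table["observed"] = table["year"].map(dict(observed))
    return table
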