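"""Seeded synthetic data emulating the model's three input kinds.

Real inputs (OECD/AIHW-style region tables, ABS-style subgroup panels,
ONS-style monthly death series) are not redistributable, so every analysis
here is exercised on generated data with known truth:

* regions scattered around a chosen equivalence line with multiplicative
  noise — the benchmarking and log-linear fitting loop closes on the known
  intercept;
* a multi-region subgroup panel built from known per-death and
  per-population bed-day rates — the decomposition recovers them;
* monthly death series with a sinusoidal seasonal baseline, Poisson counts
  and optional outbreak spikes — the volatility statistics match Poisson
  theory under the null and flip sign after a spike year.

Every generator is a pure function of its config, including the seed.  Each
region/area gets its own RNG stream keyed by (seed, index), so enlarging a
dataset never reshuffles the units already generated.

Noise is multiplicative throughout: the generated quantities are positive
rates and ratios whose errors scale with their level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_RELATION,
    EquivalenceLine,
    InvalidInputError,
    QuadraticRelation,
    RegionRecord,
    equivalence_value,
)
from .decomposition import SubgroupPanelRow, SubgroupRates, predict_bed_days
from .volatility import MonthlyDeathSeries

__all__ = [
    "SyntheticRegionConfig",
    "SyntheticPanelConfig",
    "SpikeSpec",
    "generate_regions",
    "generate_subgroup_panel",
    "generate_monthly_deaths",
]


def _rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for unit ``index`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), index]))


# ---------------------------------------------------------------------------
# Regions around an equivalence line
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRegionConfig:
    """Regions scattered around one line of equivalence.

    x (deaths per 1000 population) is uniform over ``x_range``; y is the
    line value times a multiplicative Normal(1, noise_sd) factor.
    Population, deaths and bed-days are back-solved so that re-deriving the
    ratios reproduces (x, y) exactly; counts are therefore real-valued.
    """

    n_regions: int = 50
    intercept: float = 800.0
    x_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.02
    population_range: tuple[float, float] = (200_000.0, 8_000_000.0)
    seed: int = 0
    relation: QuadraticRelation = field(default=DEFAULT_RELATION)

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise InvalidInputError("n_regions must be >= 1")
        if not (0 < self.x_range[0] <= self.x_range[1]):
            raise InvalidInputError(
                f"x_range must satisfy 0 < min <= max, got {self.x_range!r}"
            )
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.intercept <= 0:
            raise InvalidInputError("intercept must be positive")
        if not (0 < self.population_range[0] <= self.population_range[1]):
            raise InvalidInputError(
                "population_range must satisfy 0 < min <= max"
            )


def generate_regions(config: SyntheticRegionConfig) -> list[RegionRecord]:
    """Draw regions whose ratio points scatter around the configured line."""
    line = EquivalenceLine.from_intercept(config.intercept, config.relation)
    records = []
    for i in range(config.n_regions):
        rng = _rng(config.seed, i)
        x = rng.uniform(*config.x_range)
        y = equivalence_value(line, x) * (1.0 + rng.normal(0.0, config.noise_sd))
        y = max(y, 0.0)
        population = rng.uniform(*config.population_range)
        deaths = x * population / 1000.0
        occupied_beds = y * deaths / 1000.0
        records.append(
            RegionRecord(
                region_id=f"R{i:03d}",
                year="sim",
                population=population,
                deaths=deaths,
                occupied_bed_days=occupied_beds * 365.0,
                same_day_admissions=0.0,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Subgroup panels from known rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Multi-region two-group (or G-group) panel with known generating rates.

    Each region draws a total population, splits it by group shares (the
    first group's share varies across regions over ``share_range``, so the
    design has full rank and a high-share region stands out the way a
    territory with a large indigenous population does), applies per-group
    crude death rates, and computes total bed-days from ``true_rates`` with
    multiplicative noise.
    """

    n_regions: int = 8
    true_rates: SubgroupRates = field(
        default_factory=lambda: SubgroupRates(
            groups=("indigenous", "non_indigenous"),
            per_1000_deaths=(1509.0, 429.0),
            per_1000_population=(90.0, 15.0),
        )
    )
    #: Range over which the first group's population share varies by region
    #: (Australian jurisdictions span ~2% to ~30% indigenous share).
    share_range: tuple[float, float] = (0.02, 0.35)
    #: Crude death rate (deaths per 1000 population) per group.
    death_rates: tuple[float, ...] = (7.0, 6.5)
    #: Per-region multiplicative spread on each group's death rate, one
    #: (low, high) range per group.  Regions differ in age structure and
    #: remoteness, so crude rates vary around the group base; without this
    #: variation group deaths would be exactly proportional to group
    #: population and the per-death/per-population split would be
    #: unidentifiable.  The spread is deliberately at the wide end of what
    #: demography allows (first group ~4-14, second ~4.5-9 deaths per 1000)
    #: because the panel's purpose is rate recovery: the wider the
    #: death-rate variation, the better conditioned the design matrix.
    death_rate_rel_ranges: tuple[tuple[float, float], ...] = (
        (0.6, 2.0),
        (0.7, 1.4),
    )
    #: Populations are drawn log-uniformly: jurisdiction sizes span orders
    #: of magnitude, and small high-share regions carry the design leverage.
    population_range: tuple[float, float] = (150_000.0, 6_000_000.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.true_rates.groups)
        if self.n_regions < 1:
            raise InvalidInputError("n_regions must be >= 1")
        if len(self.death_rates) != g:
            raise InvalidInputError(
                f"death_rates must have one entry per group ({g})"
            )
        if any(d <= 0 or d > 1000 for d in self.death_rates):
            raise InvalidInputError(
                "death_rates must be in (0, 1000] per 1000 population"
            )
        if len(self.death_rate_rel_ranges) != g:
            raise InvalidInputError(
                f"death_rate_rel_ranges must have one (low, high) per group ({g})"
            )
        for lo, hi in self.death_rate_rel_ranges:
            if not 0 < lo <= hi:
                raise InvalidInputError(
                    "each death_rate_rel_range must satisfy 0 < low <= high"
                )
        if g >= 2 and not (0 < self.share_range[0] <= self.share_range[1] < 1):
            raise InvalidInputError(
                "share_range must satisfy 0 < min <= max < 1"
            )
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not (0 < self.population_range[0] <= self.population_range[1]):
            raise InvalidInputError(
                "population_range must satisfy 0 < min <= max"
            )


def generate_subgroup_panel(
    config: SyntheticPanelConfig,
) -> list[SubgroupPanelRow]:
    """Draw a panel whose total bed-days follow the configured true rates."""
    rates = config.true_rates
    g = len(rates.groups)
    rows = []
    for i in range(config.n_regions):
        rng = _rng(config.seed, i)
        lo, hi = config.population_range
        total_pop = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if g >= 2:
            first_share = rng.uniform(*config.share_range)
            rest = (1.0 - first_share) / (g - 1)
            shares = [first_share] + [rest] * (g - 1)
        else:
            shares = [1.0]
        pops = tuple(total_pop * s for s in shares)
        rate_factors = [
            rng.uniform(lo, hi) for lo, hi in config.death_rate_rel_ranges
        ]
        deaths = tuple(
            p * d * f / 1000.0
            for p, d, f in zip(pops, config.death_rates, rate_factors)
        )
        row = SubgroupPanelRow(
            region_id=f"P{i:03d}",
            groups=rates.groups,
            populations=pops,
            deaths=deaths,
            total_occupied_bed_days=0.0,
        )
        bed_days = predict_bed_days(row, rates)
        if config.noise_sd > 0:
            bed_days *= max(1.0 + rng.normal(0.0, config.noise_sd), 0.0)
        rows.append(
            SubgroupPanelRow(
                region_id=row.region_id,
                groups=row.groups,
                populations=row.populations,
                deaths=row.deaths,
                total_occupied_bed_days=bed_days,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Monthly death series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeSpec:
    """A multiplicative outbreak window applied to the seasonal mean."""

    start_month: str          # "YYYY-MM"
    n_months: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise InvalidInputError("spike n_months must be >= 1")
        if self.multiplier <= 0:
            raise InvalidInputError("spike multiplier must be positive")


def generate_monthly_deaths(
    n_areas: int,
    months: Sequence[str],
    baseline_mean: float = 125.0,
    seasonal_amplitude: float = 0.15,
    spike_spec: Sequence[SpikeSpec] = (),
    seed: int = 0,
    deterministic_means: bool = False,
) -> list[MonthlyDeathSeries]:
    """Poisson monthly death counts with seasonality and optional spikes.

    The expected count in calendar month m is

        baseline_mean * (1 + amplitude * cos(2*pi*(m - 1)/12)) * spike(m)

    peaking in January, the northern-hemisphere mortality peak.  The default
    baseline of 125/month (~1500/year) matches a median UK local-authority
    area.  With ``deterministic_means`` the expectations themselves are
    returned (no Poisson draw), which makes window totals exactly analytic.
    """
    if n_areas < 1:
        raise InvalidInputError("n_areas must be >= 1")
    if baseline_mean <= 0:
        raise InvalidInputError("baseline_mean must be positive")
    if not 0 <= seasonal_amplitude < 1:
        raise InvalidInputError("seasonal_amplitude must be in [0, 1)")
    idx = pd.PeriodIndex(list(months), freq="M")
    if len(idx) == 0:
        raise InvalidInputError("months must be non-empty")
    if len(idx) > 1 and not (np.diff(idx.asi8) == 1).all():
        raise InvalidInputError("months must be contiguous")
    month_of_year = idx.month.to_numpy()
    mean = baseline_mean * (
        1.0 + seasonal_amplitude * np.cos(2.0 * np.pi * (month_of_year - 1) / 12.0)
    )
    for spike in spike_spec:
        start = pd.Period(spike.start_month, freq="M")
        offsets = idx.asi8 - start.ordinal
        in_window = (offsets >= 0) & (offsets < spike.n_months)
        mean = np.where(in_window, mean * spike.multiplier, mean)
    labels = tuple(str(p) for p in idx)
    areas = []
    for i in range(n_areas):
        if deterministic_means:
            counts = mean.astype(float)
        else:
            counts = _rng(seed, i).poisson(mean).astype(float)
        areas.append(
            MonthlyDeathSeries(
                area_id=f"A{i:04d}", months=labels, deaths=tuple(counts)
            )
        )
    return areas
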