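"""Logarithmic benchmarking of hospital bed provision against deaths.

The central empirical fact is the nearness-to-death effect: roughly 55% of a
person's lifetime hospital bed use falls in the last year of life, largely
independent of the age at death.  Annual deaths therefore predict acute bed
demand far better than population size alone, and regions can be compared on
two ratios:

* ``x`` — deaths per 1000 population (the crude mortality rate, a proxy for
  the population age structure), and
* ``y`` — occupied (or available) beds per 1000 deaths.

Across countries and regions these follow a natural-log relationship
``y = a + b * ln(x)``.  The slope ``b`` is not free: it is tied to the
intercept ``a`` by a quadratic through the origin,

    b = c2 * a**2 + c1 * a,        c2 = 0.000008756, c1 = -0.29322,

so a single number — the intercept, the beds-per-1000-deaths value at one
death per 1000 population — indexes an entire *line of equivalence*.  Regions
on the same line have equivalent bed provision once age structure is
accounted for; a region's percentage deviation from a reference line is the
benchmarking statistic.

All logarithms here are natural logarithms.  All rates are kept per-1000
internally; conversion to per-capita or absolute numbers happens only at the
operation boundaries that need it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DAYS_PER_YEAR",
    "DEFAULT_SAME_DAY_STAY_DAYS",
    "DEFAULT_RELATION",
    "BedbenchError",
    "InvalidInputError",
    "UndefinedRatioError",
    "DomainError",
    "DegenerateLineError",
    "NoSolutionError",
    "UnderdeterminedError",
    "InsufficientDataError",
    "SchemaError",
    "ParseError",
    "RegionRecord",
    "RatioPoint",
    "QuadraticRelation",
    "EquivalenceLine",
    "LogLinearFit",
    "deaths_per_1000_population",
    "beds_per_1000_deaths",
    "occupied_beds_from_bed_days",
    "adjust_for_same_day",
    "slope_from_intercept",
    "equivalence_value",
    "deviation_pct",
    "implied_intercept",
    "predict_occupied_beds",
    "predict_occupied_beds_folded",
    "fit_loglinear",
    "fit_slope_intercept_relation",
    "births_per_death",
    "region_ratio_point",
    "benchmark_regions",
]

logger = logging.getLogger("bedbench")

#: Days used to convert annual occupied bed-days into average occupied beds.
DAYS_PER_YEAR = 365.0

#: Bed-days assigned to a same-day admission (an 8-hour stay, printed as
#: 0.35 days in the source accounting convention; kept as printed, not 8/24).
DEFAULT_SAME_DAY_STAY_DAYS = 0.35


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class BedbenchError(Exception):
    """Base class for all bedbench errors."""


class InvalidInputError(BedbenchError, ValueError):
    """An input violates a precondition (negative count, zero population...)."""


class UndefinedRatioError(BedbenchError, ZeroDivisionError):
    """A ratio with zero denominator (deaths = 0); the unit must be excluded."""


class DomainError(BedbenchError, ValueError):
    """Argument outside the mathematical domain (e.g. ln of x <= 0)."""


class DegenerateLineError(BedbenchError, ValueError):
    """An equivalence line is non-positive at the requested x."""


class NoSolutionError(BedbenchError, ValueError):
    """No admissible intercept solves the inversion problem."""


class UnderdeterminedError(BedbenchError, ValueError):
    """Too few observations (or a rank-deficient design) for a fit."""


class InsufficientDataError(BedbenchError, ValueError):
    """Not enough data to compute the requested statistic."""


class SchemaError(BedbenchError, ValueError):
    """Structurally mismatched inputs (group sets differ, bad columns...)."""


class ParseError(BedbenchError, ValueError):
    """A delimited-text input could not be parsed; carries row diagnostics."""

    def __init__(self, message: str, row_errors: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.row_errors = list(row_errors)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _require_nonneg(name: str, value: float | None) -> None:
    if value is not None and value < 0:
        raise InvalidInputError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class RegionRecord:
    """One region-year of population, deaths and bed utilization.

    Counts are stored raw (persons, deaths, bed-days); operations convert to
    per-1000 rates where the model requires.  ``occupied_bed_days`` and
    ``available_beds`` are optional because sources report one or the other.
    """

    region_id: str
    year: str
    population: float
    deaths: float
    occupied_bed_days: float | None = None
    same_day_admissions: float = 0.0
    available_beds: float | None = None

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise InvalidInputError(
                f"population must be positive, got {self.population!r} "
                f"(region {self.region_id!r})"
            )
        _require_nonneg("deaths", self.deaths)
        _require_nonneg("occupied_bed_days", self.occupied_bed_days)
        _require_nonneg("same_day_admissions", self.same_day_admissions)
        _require_nonneg("available_beds", self.available_beds)
        if self.deaths > self.population:
            raise InvalidInputError(
                f"deaths ({self.deaths}) exceed population ({self.population}) "
                f"in region {self.region_id!r}"
            )


@dataclass(frozen=True)
class RatioPoint:
    """A region reduced to the model's two axes.

    ``deaths_per_1000_pop`` is x (must be positive so ln(x) exists);
    ``beds_per_1000_deaths`` is y.
    """

    deaths_per_1000_pop: float
    beds_per_1000_deaths: float

    def __post_init__(self) -> None:
        if self.deaths_per_1000_pop <= 0:
            raise InvalidInputError(
                "deaths_per_1000_pop must be positive (ln(x) must exist), "
                f"got {self.deaths_per_1000_pop!r}"
            )
        _require_nonneg("beds_per_1000_deaths", self.beds_per_1000_deaths)


@dataclass(frozen=True)
class QuadraticRelation:
    """Coefficients tying an equivalence line's slope to its intercept.

    slope = c2 * intercept**2 + c1 * intercept.  The defaults are the fitted
    through-origin values for hospital beds across world countries; c1 < 0
    and c2 > 0 make the slope negative for every intercept below
    ``-c1/c2`` (~33,500 beds per 1000 deaths), i.e. for every realistic line.
    """

    c2: float = 0.000008756
    c1: float = -0.29322

    @property
    def max_negative_slope_intercept(self) -> float:
        """Upper end of the intercept interval on which slopes are negative."""
        return -self.c1 / self.c2


DEFAULT_RELATION = QuadraticRelation()


@dataclass(frozen=True)
class EquivalenceLine:
    """A line of equivalent bed provision: y = intercept + slope * ln(x).

    The slope is derived from the intercept via a :class:`QuadraticRelation`
    and stored for reuse; construct lines with :meth:`from_intercept` so the
    two stay consistent.
    """

    intercept: float
    slope: float
    relation: QuadraticRelation = field(default=DEFAULT_RELATION, compare=False)

    @classmethod
    def from_intercept(
        cls, intercept: float, relation: QuadraticRelation = DEFAULT_RELATION
    ) -> "EquivalenceLine":
        if intercept <= 0:
            raise InvalidInputError(
                f"intercept must be positive, got {intercept!r}"
            )
        return cls(
            intercept=intercept,
            slope=slope_from_intercept(intercept, relation),
            relation=relation,
        )


class LogLinearFit(NamedTuple):
    """OLS fit of beds per 1000 deaths on ln(deaths per 1000 population)."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    rss: float


# ---------------------------------------------------------------------------
# Ratio construction and unit conversions
# ---------------------------------------------------------------------------

def deaths_per_1000_population(record: RegionRecord) -> float:
    """Crude mortality rate: 1000 * deaths / population.

    Acts as the model's proxy for population age structure (x axis).
    """
    if record.population <= 0:
        raise InvalidInputError("population must be positive")
    return 1000.0 * record.deaths / record.population


def beds_per_1000_deaths(beds: float, deaths: float) -> float:
    """Beds (occupied or available) per 1000 deaths: 1000 * beds / deaths.

    Algebraically identical to dividing beds per 1000 population by deaths
    per 1000 population (times 1000); both routes agree to floating error.

    Raises
    ------
    UndefinedRatioError
        If ``deaths`` is zero — the region must be excluded, not imputed.
    """
    _require_nonneg("beds", beds)
    if deaths < 0:
        raise InvalidInputError(f"deaths must be non-negative, got {deaths!r}")
    if deaths == 0:
        raise UndefinedRatioError("beds per 1000 deaths undefined: deaths = 0")
    return 1000.0 * beds / deaths


def occupied_beds_from_bed_days(bed_days: float) -> float:
    """Average occupied beds over a year: annual bed-days / 365.

    Works on any bed-day quantity on a per-year basis, including bed-days
    per 1000 deaths or per 1000 population (the result keeps the same
    denominator: 1509 bed-days per 1000 deaths -> 4.13 occupied beds per
    1000 deaths).
    """
    _require_nonneg("bed_days", bed_days)
    return bed_days / DAYS_PER_YEAR


def adjust_for_same_day(
    bed_days: float,
    same_day_admissions: float,
    stay_fraction: float = DEFAULT_SAME_DAY_STAY_DAYS,
) -> float:
    """Add same-day admissions to midnight-census bed-days.

    Midnight occupancy counts miss admissions discharged the same day; each
    is assigned ``stay_fraction`` bed-days (default 0.35, an 8-hour stay).
    """
    _require_nonneg("bed_days", bed_days)
    _require_nonneg("same_day_admissions", same_day_admissions)
    _require_nonneg("stay_fraction", stay_fraction)
    return bed_days + stay_fraction * same_day_admissions


def births_per_death(births: float, deaths: float) -> float:
    """Ratio of annual births to annual deaths for an area.

    Areas above ~2.5 births per death are dominated by maternity and
    paediatric demand, which does not follow the nearness-to-death effect.
    """
    _require_nonneg("births", births)
    if deaths < 0:
        raise InvalidInputError(f"deaths must be non-negative, got {deaths!r}")
    if deaths == 0:
        raise UndefinedRatioError("births per death undefined: deaths = 0")
    return births / deaths


# ---------------------------------------------------------------------------
# Lines of equivalence
# ---------------------------------------------------------------------------

def slope_from_intercept(
    intercept: float, relation: QuadraticRelation = DEFAULT_RELATION
) -> float:
    """Slope implied by an intercept: c2 * a**2 + c1 * a (0 at the origin)."""
    if intercept < 0:
        raise InvalidInputError(f"intercept must be >= 0, got {intercept!r}")
    return relation.c2 * intercept**2 + relation.c1 * intercept


def equivalence_value(line: EquivalenceLine, x: float) -> float:
    """Beds per 1000 deaths on ``line`` at crude mortality ``x``.

    y = a + b * ln(x); at x = 1 this is exactly the intercept.
    """
    if x <= 0:
        raise DomainError(f"deaths per 1000 population must be > 0, got {x!r}")
    return line.intercept + line.slope * math.log(x)


def deviation_pct(observed_y: float, line: EquivalenceLine, x: float) -> float:
    """Percentage deviation of an observed y from an equivalence line.

    100 * (observed - line) / line; negative means fewer beds than the line
    (a bed deficit), positive means more.
    """
    line_y = equivalence_value(line, x)
    if line_y <= 0:
        raise DegenerateLineError(
            f"equivalence line (intercept {line.intercept}) is non-positive "
            f"at x = {x}; deviation undefined"
        )
    return 100.0 * (observed_y - line_y) / line_y


def implied_intercept(
    x: float, y: float, relation: QuadraticRelation = DEFAULT_RELATION
) -> float:
    """Intercept of the equivalence line passing through (x, y).

    Inverts y = a + (c2*a**2 + c1*a) * ln(x), i.e. solves

        c2*ln(x) * a**2 + (1 + c1*ln(x)) * a - y = 0

    for a.  The admissible root is the one in (0, -c1/c2), the interval on
    which lines slope downward and are physically meaningful; if both or
    neither root lies there the inversion fails.  At x = 1 the answer is y
    itself.
    """
    if x <= 0:
        raise DomainError(f"x must be > 0, got {x!r}")
    if y <= 0:
        raise InvalidInputError(f"y must be > 0, got {y!r}")
    lx = math.log(x)
    qa = relation.c2 * lx           # quadratic coefficient
    qb = 1.0 + relation.c1 * lx     # linear coefficient
    upper = relation.max_negative_slope_intercept
    if abs(qa) < 1e-12:
        # x ~ 1 (or c2 = 0): the equation is linear in a.
        if abs(qb) < 1e-12:
            raise NoSolutionError("degenerate inversion: both coefficients ~ 0")
        a = y / qb
        if not 0.0 < a < upper:
            raise NoSolutionError(
                f"linear-case intercept {a:.6g} outside (0, {upper:.6g})"
            )
        return a
    disc = qb * qb + 4.0 * qa * y
    if disc < 0:
        raise NoSolutionError(f"no real intercept for x={x}, y={y}")
    sq = math.sqrt(disc)
    # Numerically stable quadratic roots (avoid cancellation in -qb ± sq);
    # the second root comes from the product a1*a2 = -y/qa.
    q = -0.5 * (qb + math.copysign(sq, qb))
    roots = [q / qa]
    if q != 0.0:
        roots.append(-y / q)
    admissible = sorted({r for r in roots if 0.0 < r < upper})
    if len(admissible) != 1:
        raise NoSolutionError(
            f"expected exactly one intercept in (0, {upper:.6g}) for "
            f"x={x}, y={y}; found {len(admissible)}: {admissible}"
        )
    return admissible[0]


def predict_occupied_beds(
    deaths_thousands: float,
    population_thousands: float,
    line: EquivalenceLine,
) -> float:
    """Absolute occupied beds implied by an equivalence line.

    With D = deaths and P = population, both in thousands, the crude
    mortality rate is x = 1000*D/P and the line gives y beds per 1000
    deaths, so occupied beds = y * (1000*D)/1000 = D * y.
    """
    if deaths_thousands <= 0 or population_thousands <= 0:
        raise InvalidInputError("deaths and population must be positive")
    if deaths_thousands >= population_thousands:
        raise InvalidInputError("deaths must be smaller than population")
    x = 1000.0 * deaths_thousands / population_thousands
    return deaths_thousands * equivalence_value(line, x)


def predict_occupied_beds_folded(
    deaths_thousands: float,
    population_thousands: float,
    line: EquivalenceLine,
) -> float:
    """Occupied beds via the rearranged form D * [a' + b'*ln(P) - b'*ln(D)].

    Folding the per-1000 scaling into the constants — a' = a + b*ln(1000),
    b' = -b — turns ``D * (a + b*ln(1000*D/P))`` into the form above.  This
    is algebraically identical to :func:`predict_occupied_beds`; it exists
    to document the folding and is verified against the direct route in the
    test suite.
    """
    if deaths_thousands <= 0 or population_thousands <= 0:
        raise InvalidInputError("deaths and population must be positive")
    if deaths_thousands >= population_thousands:
        raise InvalidInputError("deaths must be smaller than population")
    a_f = line.intercept + line.slope * math.log(1000.0)
    b_f = -line.slope
    return deaths_thousands * (
        a_f
        + b_f * math.log(population_thousands)
        - b_f * math.log(deaths_thousands)
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_loglinear(points: Sequence[RatioPoint]) -> LogLinearFit:
    """Ordinary least squares of y on ln(x) over ratio points.

    Returns the intercept (value at x = 1, i.e. at one death per 1000
    population) and the slope per natural-log unit, with their standard
    errors and the residual sum of squares.  Weighting is uniform; grouping
    of regions into comparable sets is the caller's responsibility.
    """
    if len(points) < 2:
        raise UnderdeterminedError("need at least 2 points to fit a line")
    x = np.array([p.deaths_per_1000_pop for p in points], dtype=float)
    y = np.array([p.beds_per_1000_deaths for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise UnderdeterminedError("need at least 2 distinct x values")
    design = sm.add_constant(np.log(x))
    res = sm.OLS(y, design).fit()
    return LogLinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        rss=float(res.ssr),
    )


def fit_slope_intercept_relation(
    pairs: Sequence[tuple[float, float]],
) -> QuadraticRelation:
    """Through-origin least-squares fit of slope on (intercept^2, intercept).

    Each pair is (intercept, slope) from an independently fitted log-linear
    relation; the quadratic has no constant term, so a zero intercept maps
    to a zero slope exactly.
    """
    if len(pairs) < 2:
        raise UnderdeterminedError("need at least 2 (intercept, slope) pairs")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(a).size < 2:
        raise UnderdeterminedError("need at least 2 distinct intercepts")
    design = np.column_stack([a**2, a])
    if np.linalg.matrix_rank(design) < 2:
        raise UnderdeterminedError(
            "rank-deficient design: intercepts do not separate a^2 from a"
        )
    res = sm.OLS(b, design).fit()
    return QuadraticRelation(c2=float(res.params[0]), c1=float(res.params[1]))


# ---------------------------------------------------------------------------
# Region-level benchmarking pipeline
# ---------------------------------------------------------------------------

def region_ratio_point(
    record: RegionRecord,
    same_day_stay_days: float = DEFAULT_SAME_DAY_STAY_DAYS,
    bed_measure: str = "occupied",
) -> RatioPoint:
    """Reduce a region-year to its (x, y) ratio point.

    For ``bed_measure="occupied"``, bed-days are first adjusted for
    same-day admissions and then divided by 365; for ``"available"``, the
    reported bed count is used directly.

    Raises
    ------
    UndefinedRatioError
        If the region recorded zero deaths.
    InvalidInputError
        If the requested bed measure is missing from the record.
    """
    if bed_measure == "occupied":
        if record.occupied_bed_days is None:
            raise InvalidInputError(
                f"region {record.region_id!r} has no occupied_bed_days"
            )
        bed_days = adjust_for_same_day(
            record.occupied_bed_days, record.same_day_admissions,
            same_day_stay_days,
        )
        beds = occupied_beds_from_bed_days(bed_days)
    elif bed_measure == "available":
        if record.available_beds is None:
            raise InvalidInputError(
                f"region {record.region_id!r} has no available_beds"
            )
        beds = record.available_beds
    else:
        raise InvalidInputError(
            f"bed_measure must be 'occupied' or 'available', got {bed_measure!r}"
        )
    return RatioPoint(
        deaths_per_1000_pop=deaths_per_1000_population(record),
        beds_per_1000_deaths=beds_per_1000_deaths(beds, record.deaths),
    )


def benchmark_regions(
    records: Sequence[RegionRecord],
    intercepts: Sequence[float],
    relation: QuadraticRelation = DEFAULT_RELATION,
    same_day_stay_days: float = DEFAULT_SAME_DAY_STAY_DAYS,
    bed_measure: str = "occupied",
) -> tuple[pd.DataFrame, list[str]]:
    """Score every region against each requested equivalence line.

    Returns a tidy frame with one row per (region, line): region_id, x, y,
    implied_intercept, line_intercept, deviation_pct — plus the list of
    excluded region ids (zero deaths, or missing bed measure), which are
    logged as warnings rather than failing the run.
    """
    lines = [EquivalenceLine.from_intercept(a, relation) for a in intercepts]
    rows: list[dict] = []
    excluded: list[str] = []
    for rec in records:
        try:
            pt = region_ratio_point(rec, same_day_stay_days, bed_measure)
        except (UndefinedRatioError, InvalidInputError) as exc:
            logger.warning("excluding region %r: %s", rec.region_id, exc)
            excluded.append(rec.region_id)
            continue
        x, y = pt.deaths_per_1000_pop, pt.beds_per_1000_deaths
        try:
            implied = implied_intercept(x, y, relation)
        except (NoSolutionError, InvalidInputError):
            implied = math.nan
        for line in lines:
            rows.append(
                {
                    "region_id": rec.region_id,
                    "x": x,
                    "y": y,
                    "implied_intercept": implied,
                    "line_intercept": line.intercept,
                    "deviation_pct": deviation_pct(y, line, x),
                }
            )
    columns = [
        "region_id", "x", "y", "implied_intercept",
        "line_intercept", "deviation_pct",
    ]
    return pd.DataFrame(rows, columns=columns), excluded
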