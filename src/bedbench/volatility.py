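"""Rolling 12-month mortality totals and small-area volatility statistics.

A rolling (moving) 12-month total of monthly deaths always spans all four
seasons, so seasonality cancels.  Comparing each 12-month block with the
immediately preceding, non-overlapping 12-month block — e.g. April 2021 to
March 2022 against April 2020 to March 2021 — gives a percentage difference
series whose sign tracks outbreak timing: a heavy epidemic year followed by
a normal one yields negative differences.

Aggregating those differences across many small areas (quartiles by month)
shows whether year-to-year swings exceed what count noise alone allows.  The
Poisson yardstick: an area with n deaths per year has a one-standard-
deviation count fluctuation of 100/sqrt(n) percent (±3.2% at n = 1000,
±2.6% at n = 1500), so quartile bands much wider than that indicate
systematic, not random, variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DomainError, InsufficientDataError, InvalidInputError

__all__ = [
    "MonthlyDeathSeries",
    "QuantileResult",
    "rolling_12m_total",
    "adjacent_12m_diff_pct",
    "cross_area_quantiles",
    "quantile_table",
    "poisson_sd_pct",
]

WINDOW = 12


@dataclass(frozen=True)
class MonthlyDeathSeries:
    """Monthly all-cause deaths for one area.

    ``months`` are "YYYY-MM" labels, strictly increasing with no gaps.
    Counts must be non-negative; non-integer values are accepted so that
    deterministic expected-count series can flow through the same code path.
    """

    area_id: str
    months: tuple[str, ...]
    deaths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.deaths):
            raise InvalidInputError(
                f"area {self.area_id!r}: {len(self.months)} months but "
                f"{len(self.deaths)} death counts"
            )
        if len(self.months) == 0:
            raise InvalidInputError(f"area {self.area_id!r}: empty series")
        try:
            idx = pd.PeriodIndex(list(self.months), freq="M")
        except Exception as exc:
            raise InvalidInputError(
                f"area {self.area_id!r}: months must be YYYY-MM labels: {exc}"
            ) from exc
        gaps = np.diff(idx.asi8)
        if len(gaps) and not (gaps == 1).all():
            raise InvalidInputError(
                f"area {self.area_id!r}: months must be contiguous and "
                "strictly increasing"
            )
        for m, d in zip(self.months, self.deaths):
            if not math.isfinite(d) or d < 0:
                raise InvalidInputError(
                    f"area {self.area_id!r}, month {m}: deaths must be a "
                    f"non-negative finite number, got {d!r}"
                )

    def __len__(self) -> int:
        return len(self.months)

    def to_series(self) -> pd.Series:
        return pd.Series(
            list(self.deaths),
            index=pd.PeriodIndex(list(self.months), freq="M"),
            name=self.area_id,
            dtype=float,
        )


@dataclass(frozen=True)
class QuantileResult:
    """Cross-area quantiles of the adjacent-block difference at one month."""

    month: str
    quantiles: dict[float, float]
    n_areas: int
    n_excluded: int


def rolling_12m_total(series: MonthlyDeathSeries) -> pd.Series:
    """Rolling 12-month death totals, indexed by each window's last month.

    The first 11 months have no complete window and are dropped, not
    padded; output length is input length minus 11.
    """
    if len(series) < WINDOW:
        raise InsufficientDataError(
            f"area {series.area_id!r}: need >= {WINDOW} months, "
            f"got {len(series)}"
        )
    s = series.to_series()
    return s.rolling(WINDOW).sum().dropna()


def adjacent_12m_diff_pct(series: MonthlyDeathSeries) -> pd.Series:
    """Percent difference between adjacent non-overlapping 12-month blocks.

    For each month t from the 24th on: 100 * (T_t - T_{t-12}) / T_{t-12},
    where T is the rolling 12-month total ending at t.  A zero earlier
    block makes the difference undefined at that month; it is emitted as
    NaN rather than raising, so sparse areas degrade gracefully.
    """
    if len(series) < 2 * WINDOW:
        raise InsufficientDataError(
            f"area {series.area_id!r}: need >= {2 * WINDOW} months for an "
            f"adjacent-block difference, got {len(series)}"
        )
    totals = rolling_12m_total(series)
    current = totals.iloc[WINDOW:]
    previous = totals.shift(WINDOW).iloc[WINDOW:]
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = 100.0 * (current - previous) / previous
    return diff.where(previous != 0, other=np.nan)


def cross_area_quantiles(
    collection: Sequence[MonthlyDeathSeries],
    month: str,
    probs: Sequence[float] = (0.25, 0.75),
) -> QuantileResult:
    """Quantiles of the adjacent-block difference across areas at one month.

    Areas whose difference is undefined at ``month`` (too-short series,
    month outside their range, zero denominator) are excluded and counted
    in ``n_excluded``.  Quantiles use linear interpolation between order
    statistics (numpy's default, the type-7 convention).
    """
    period = pd.Period(month, freq="M")
    values: list[float] = []
    n_excluded = 0
    for series in collection:
        try:
            diff = adjacent_12m_diff_pct(series)
        except InsufficientDataError:
            n_excluded += 1
            continue
        if period not in diff.index or not math.isfinite(diff[period]):
            n_excluded += 1
            continue
        values.append(float(diff[period]))
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >= 2 areas with a defined difference at {month}, "
            f"got {len(values)}"
        )
    arr = np.array(values)
    return QuantileResult(
        month=month,
        quantiles={float(p): float(np.quantile(arr, p)) for p in probs},
        n_areas=len(values),
        n_excluded=n_excluded,
    )


def quantile_table(
    collection: Sequence[MonthlyDeathSeries],
    probs: Sequence[float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Tidy table of cross-area difference quantiles for every usable month.

    Columns: month, quantile_prob, value, n_areas, n_excluded.  Months with
    fewer than two defined areas are omitted.
    """
    diffs: list[pd.Series] = []
    n_short = 0
    for series in collection:
        try:
            diffs.append(adjacent_12m_diff_pct(series))
        except InsufficientDataError:
            n_short += 1
    if not diffs:
        raise InsufficientDataError("no area has >= 24 months of data")
    frame = pd.concat(diffs, axis=1)
    rows = []
    for period, row in frame.iterrows():
        vals = row.dropna().to_numpy()
        if len(vals) < 2:
            continue
        for p in probs:
            rows.append(
                {
                    "month": str(period),
                    "quantile_prob": float(p),
                    "value": float(np.quantile(vals, p)),
                    "n_areas": len(vals),
                    "n_excluded": n_short + (len(frame.columns) - len(vals)),
                }
            )
    if not rows:
        raise InsufficientDataError(
            "no month has >= 2 areas with a defined difference"
        )
    return pd.DataFrame(
        rows,
        columns=["month", "quantile_prob", "value", "n_areas", "n_excluded"],
    )


def poisson_sd_pct(annual_deaths: float) -> float:
    """One standard deviation of Poisson count noise, as a percentage.

    For an annual total n, sd(n)/n = sqrt(n)/n, i.e. 100/sqrt(n) percent:
    ~3.2% at 1000 deaths per year, ~2.6% at 1500.
    """
    if annual_deaths <= 0:
        raise DomainError(
            f"annual deaths must be positive, got {annual_deaths!r}"
        )
    return 100.0 / math.sqrt(annual_deaths)
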