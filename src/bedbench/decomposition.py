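"""Splitting total occupied bed-days across population subgroups.

Total annual occupied bed-days in a region are modelled as a sum over
population groups (e.g. indigenous / non-indigenous Australians) of a
per-death component and a per-population component:

    bed_days = sum_g [ beta_d[g] * deaths_g / 1000
                       + beta_p[g] * population_g / 1000 ]

``beta_d[g]`` is bed-days per 1000 deaths in group g (the nearness-to-death
component) and ``beta_p[g]`` is bed-days per 1000 population (the age/
morbidity component).  The rates are estimated by minimising the squared
difference between actual and predicted bed-days across regions, subject to
non-negativity, with any subset of rates held fixed — mirroring a
spreadsheet-Solver workflow in which one poorly identified rate is pinned
after initial trials (e.g. the non-indigenous per-population rate at 15
bed-days per 1000 population).

The squared-error problem is linear in the rates and convex; the fitter
nevertheless runs a bound-constrained local optimizer from the supplied
initial values with a handful of seeded restarts, so the workflow (and its
diagnostics) carries over unchanged to the optional absolute-error
objective, which is not smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import InvalidInputError, SchemaError, UnderdeterminedError

__all__ = [
    "SubgroupPanelRow",
    "SubgroupRates",
    "SubgroupFitResult",
    "predict_bed_days",
    "fit_subgroup_rates",
]


@dataclass(frozen=True)
class SubgroupPanelRow:
    """One region's group populations, group deaths and total bed-days."""

    region_id: str
    groups: tuple[str, ...]
    populations: tuple[float, ...]
    deaths: tuple[float, ...]
    total_occupied_bed_days: float
    #: Set when group deaths come from a different year basis than bed-days
    #: (e.g. calendar-year deaths against financial-year utilisation).
    year_basis_mismatch: bool = False

    def __post_init__(self) -> None:
        g = len(self.groups)
        if g < 1:
            raise SchemaError("panel row needs at least one group")
        if len(self.populations) != g or len(self.deaths) != g:
            raise SchemaError(
                f"region {self.region_id!r}: populations/deaths length "
                f"does not match {g} groups"
            )
        if len(set(self.groups)) != g:
            raise SchemaError(f"region {self.region_id!r}: duplicate groups")
        for name, pop, dth in zip(self.groups, self.populations, self.deaths):
            if pop <= 0:
                raise InvalidInputError(
                    f"group {name!r} population must be positive, got {pop!r}"
                )
            if dth < 0:
                raise InvalidInputError(
                    f"group {name!r} deaths must be non-negative, got {dth!r}"
                )
            if dth > pop:
                raise InvalidInputError(
                    f"group {name!r} deaths ({dth}) exceed population ({pop})"
                )
        if self.total_occupied_bed_days < 0:
            raise InvalidInputError("total_occupied_bed_days must be >= 0")


@dataclass(frozen=True)
class SubgroupRates:
    """Per-group bed-day rates: per 1000 deaths and per 1000 population.

    ``fixed_per_1000_deaths`` / ``fixed_per_1000_population`` mark entries
    held constant during fitting; fixed entries pass through the fitter
    bit-identically.
    """

    groups: tuple[str, ...]
    per_1000_deaths: tuple[float, ...]
    per_1000_population: tuple[float, ...]
    fixed_per_1000_deaths: tuple[bool, ...] = field(default=())
    fixed_per_1000_population: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        g = len(self.groups)
        if g < 1:
            raise SchemaError("rates need at least one group")
        if len(self.per_1000_deaths) != g or len(self.per_1000_population) != g:
            raise SchemaError("rate vectors must match the number of groups")
        if not self.fixed_per_1000_deaths:
            object.__setattr__(self, "fixed_per_1000_deaths", (False,) * g)
        if not self.fixed_per_1000_population:
            object.__setattr__(self, "fixed_per_1000_population", (False,) * g)
        if (
            len(self.fixed_per_1000_deaths) != g
            or len(self.fixed_per_1000_population) != g
        ):
            raise SchemaError("fixed masks must match the number of groups")
        for r in (*self.per_1000_deaths, *self.per_1000_population):
            if r < 0:
                raise InvalidInputError(f"rates must be non-negative, got {r!r}")

    @property
    def n_free(self) -> int:
        return sum(not f for f in self.fixed_per_1000_deaths) + sum(
            not f for f in self.fixed_per_1000_population
        )

    def as_dict(self) -> dict:
        """JSON-friendly {group: {per_1000_deaths, per_1000_population, fixed...}}."""
        return {
            g: {
                "per_1000_deaths": self.per_1000_deaths[i],
                "per_1000_population": self.per_1000_population[i],
                "fixed_per_1000_deaths": self.fixed_per_1000_deaths[i],
                "fixed_per_1000_population": self.fixed_per_1000_population[i],
            }
            for i, g in enumerate(self.groups)
        }


@dataclass(frozen=True)
class SubgroupFitResult:
    """Fitted rates plus pointwise diagnostics."""

    rates: SubgroupRates
    residuals: tuple[float, ...]          # actual - predicted, per region
    objective: float
    initial_objective: float
    projected_gradient_norm: float        # squared objective only; nan for L1
    n_restarts: int


def _check_groups(row: SubgroupPanelRow, rates: SubgroupRates) -> None:
    if row.groups != rates.groups:
        raise SchemaError(
            f"region {row.region_id!r}: groups {row.groups} do not match "
            f"rate groups {rates.groups}"
        )


def predict_bed_days(row: SubgroupPanelRow, rates: SubgroupRates) -> float:
    """Model-predicted annual occupied bed-days for one region."""
    _check_groups(row, rates)
    total = 0.0
    for i in range(len(row.groups)):
        total += rates.per_1000_deaths[i] * row.deaths[i] / 1000.0
        total += rates.per_1000_population[i] * row.populations[i] / 1000.0
    return total


def _design(panel: Sequence[SubgroupPanelRow], groups: tuple[str, ...]):
    """Design matrix with one column per (group, component) rate.

    Column order matches the parameter vector: all per-1000-deaths rates
    first (group order), then all per-1000-population rates.
    """
    g = len(groups)
    m = np.empty((len(panel), 2 * g), dtype=float)
    for r, row in enumerate(panel):
        m[r, :g] = np.asarray(row.deaths) / 1000.0
        m[r, g:] = np.asarray(row.populations) / 1000.0
    return m


def fit_subgroup_rates(
    panel: Sequence[SubgroupPanelRow],
    init: SubgroupRates,
    objective: Literal["squared", "absolute"] = "squared",
    n_restarts: int = 5,
    seed: int = 0,
) -> SubgroupFitResult:
    """Estimate subgroup bed-day rates by constrained minimisation.

    Minimises the sum over regions of squared (default) or absolute
    differences between actual and predicted bed-days, subject to all rates
    being non-negative and to the fixed entries of ``init`` staying at their
    initial values.  ``n_restarts`` perturbed starts (seeded, deterministic)
    guard against poor starting points; the best solution is returned.

    Raises
    ------
    UnderdeterminedError
        If there are fewer regions than free rates, or the free columns of
        the design matrix are collinear (e.g. a single region cannot
        identify three free rates).
    """
    if not panel:
        raise UnderdeterminedError("empty panel")
    groups = init.groups
    if len(groups) < 2:
        raise SchemaError(
            "decomposition needs at least 2 groups; a single-group panel "
            "has nothing to split"
        )
    for row in panel:
        _check_groups(row, init)
    g = len(groups)
    full = np.concatenate(
        [np.asarray(init.per_1000_deaths, float),
         np.asarray(init.per_1000_population, float)]
    )
    fixed = np.concatenate(
        [np.asarray(init.fixed_per_1000_deaths, bool),
         np.asarray(init.fixed_per_1000_population, bool)]
    )
    free = ~fixed
    n_free = int(free.sum())
    m = _design(panel, groups)
    actual = np.array([r.total_occupied_bed_days for r in panel], float)

    if n_free == 0:
        # Pure prediction/residual report: nothing to optimise.
        resid = actual - m @ full
        obj = float(np.sum(resid**2) if objective == "squared"
                    else np.sum(np.abs(resid)))
        return SubgroupFitResult(
            rates=init,
            residuals=tuple(resid),
            objective=obj,
            initial_objective=obj,
            projected_gradient_norm=0.0,
            n_restarts=0,
        )

    if len(panel) < n_free:
        raise UnderdeterminedError(
            f"{len(panel)} region(s) cannot identify {n_free} free rate(s); "
            "add regions or fix more rates"
        )
    m_free = m[:, free]
    if np.linalg.matrix_rank(m_free) < n_free:
        raise UnderdeterminedError(
            "collinear group columns: the free rates are not separately "
            "identifiable from this panel"
        )
    target = actual - m[:, fixed] @ full[fixed]

    if objective == "squared":
        def fun(theta):
            r = m_free @ theta - target
            return float(r @ r), 2.0 * (m_free.T @ r)
        jac = True
        method, options = "L-BFGS-B", {"maxiter": 2000, "ftol": 1e-14,
                                       "gtol": 1e-12}
    elif objective == "absolute":
        def fun(theta):
            return float(np.abs(m_free @ theta - target).sum())
        jac = None
        method, options = "Nelder-Mead", {"maxiter": 20000, "xatol": 1e-10,
                                          "fatol": 1e-12}
    else:
        raise InvalidInputError(
            f"objective must be 'squared' or 'absolute', got {objective!r}"
        )

    def value(theta):
        out = fun(theta)
        return out[0] if jac else out

    bounds = [(0.0, None)] * n_free
    theta0 = full[free].copy()
    initial_objective = value(theta0)
    # Restart scale: the data's own magnitude, so perturbations explore a
    # relevant region even from an all-zero init.
    scale = np.maximum(np.abs(theta0), np.median(np.abs(target)) /
                       max(np.abs(m_free).mean(), 1e-12))
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        np.clip(theta0 + rng.normal(0.0, 1.0, n_free) * 0.5 * scale, 0.0, None)
        for _ in range(max(0, n_restarts - 1))
    ]
    best_theta, best_obj = None, np.inf
    for s in starts:
        res = minimize(fun, s, jac=jac, bounds=bounds, method=method,
                       options=options)
        obj = float(res.fun)
        if obj < best_obj:
            best_obj, best_theta = obj, np.asarray(res.x, float)
    # A monotone wrapper contract: the returned optimum can never be worse
    # than the supplied starting point.
    if initial_objective < best_obj:
        best_obj, best_theta = initial_objective, theta0

    full_out = full.copy()
    full_out[free] = np.clip(best_theta, 0.0, None)
    resid = actual - m @ full_out
    if objective == "squared":
        grad = 2.0 * (m_free.T @ (m_free @ full_out[free] - target))
        at_bound = full_out[free] <= 0.0
        proj = np.where(at_bound & (grad > 0), 0.0, grad)
        pg_norm = float(np.linalg.norm(proj))
    else:
        pg_norm = float("nan")

    fitted = SubgroupRates(
        groups=groups,
        per_1000_deaths=tuple(full_out[:g]),
        per_1000_population=tuple(full_out[g:]),
        fixed_per_1000_deaths=init.fixed_per_1000_deaths,
        fixed_per_1000_population=init.fixed_per_1000_population,
    )
    return SubgroupFitResult(
        rates=fitted,
        residuals=tuple(resid),
        objective=best_obj,
        initial_objective=initial_objective,
        projected_gradient_norm=pg_norm,
        n_restarts=len(starts),
    )
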