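# Methods

## The benchmarking model

Bed demand in adult acute care tracks deaths more closely than population:
about 55% of lifetime bed use falls in the last year of life regardless of
age at death, and any agent that precipitates deaths (influenza, COVID-19,
heat waves) precipitates several-fold more admissions. The model therefore
works on two ratios per region-year: `x`, deaths per 1000 population (crude
mortality rate, standing in for age structure) and `y`, beds per 1000
deaths. Empirically `y = a + b·ln(x)` with the **natural** logarithm
throughout — axis labels on log plots of this kind are easily misread as
base-10, so this is stated explicitly.

The slope and intercept of that relationship are not independent. Fitting
`(intercept, slope)` pairs from many bed datasets to a quadratic with no
constant term (a zero intercept must imply a zero slope) gives

    slope = c₂·a² + c₁·a,   c₂ = 0.000008756, c₁ = −0.29322.

For `a` between 0 and `−c₁/c₂ ≈ 33 488` the slope is negative, so every
realistic line of equivalence declines with crude mortality: younger
populations carry more beds per 1000 deaths because less of their care is
end-of-life care. One number — the intercept, `y` at `x = 1` — thus
defines a whole line, and an infinite family of lines of equivalent
provision fills the plane.

Operations built on this:

* `equivalence_value(line, x)` — the line's `y` at `x`.
* `deviation_pct(y, line, x)` — `100·(y − line)/line`; negative means
  fewer beds than the line (a deficit). The CLI rounds to whole percent in
  log messages but machine output always carries full precision.
* `implied_intercept(x, y)` — inverts `y = a + (c₂a² + c₁a)·ln(x)`,
  a quadratic in `a` with coefficient `c₂·ln(x)`. When `|c₂·ln(x)| <
  1e-12` (x at or near 1) the linear reduction is solved instead; otherwise
  both roots are formed with the numerically stable quadratic formula and
  the one inside `(0, −c₁/c₂)` is returned. If both or neither root lands
  in that interval the inversion is refused — outside it, lines slope
  upward and have no physical reading.
* `predict_occupied_beds(D, P, line)` — absolute occupied beds
  `D · equivalence_value(line, 1000·D/P)` for `D` deaths and `P`
  population in thousands. Folding the per-1000 scaling into constants,
  `a′ = a + b·ln(1000)`, `b′ = −b`, gives the equivalent form
  `D·[a′ + b′·ln(P) − b′·ln(D)]`; the identity is verified numerically to
  relative 1e-12 in the tests.
* `fit_loglinear` — unweighted OLS of `y` on `ln(x)` (statsmodels).
  Grouping regions into comparable sets is deliberately left to the caller
  rather than automated: the historical grouping of countries was an
  iterative judgment call, and the package only refits supplied groups.
* `fit_slope_intercept_relation` — through-origin OLS of slope on
  `(a², a)`, recovering `(c₂, c₁)` exactly on noiseless input.

Unit conventions: all rates are per-1000 internally; conversions happen at
operation boundaries only. Occupied beds are occupied bed-days / 365 (year
length fixed at 365; no leap-year handling). Each same-day admission adds
0.35 bed-days (an 8-hour stay as conventionally printed; the exact 8/24 =
0.333… is *not* used — the printed accounting constant wins). Regions with
zero deaths have undefined ratios and are excluded from analyses with a
logged warning rather than failing the run.

Scope: the method describes adult acute care. Maternity, paediatric and
mental-health demand follows births and age, not nearness to death — the
births-per-death ratio (areas above ~2.5 are maternity-dominated) is
provided to flag such areas — and the model is not intended for them.

## Subgroup decomposition

Total annual occupied bed-days in region `r` are modelled as

    T_r = Σ_g [ β_d(g)·deaths_{rg}/1000 + β_p(g)·pop_{rg}/1000 ]

with non-negative rates per group `g`. The fit minimises the sum of squared
differences between actual and predicted bed-days across regions ("minimise
the difference" admits several readings; squared error is the standard,
differentiable choice, with an absolute-error objective available behind
`objective="absolute"`). Any subset of rates can be held fixed — mirroring
a spreadsheet-Solver workflow where a poorly identified rate (the majority
group's per-population rate, at 15 bed-days per 1000 population) is pinned
after initial trials. Fixed entries pass through bit-identically.

The optimizer is bound-constrained L-BFGS-B from the supplied initial
values with 5 seeded restarts (Nelder-Mead for the absolute objective); the
returned solution is never worse than the starting point, and for the
squared objective the projected gradient at the solution is reported. The
squared-error problem is linear in the rates and convex, so the tests
cross-check the optimizer against an independently computed bounded linear
least-squares solution.

Identifiability is guarded explicitly: the fit is refused when there are
fewer regions than free rates (a single region cannot pin three rates — it
returns a ray of equally good solutions) or when the free design columns
are collinear. The important degenerate case is constant per-group crude
death rates, which make group deaths exactly proportional to group
population; the per-death/per-population split is then singular. Panels
mixing calendar-year deaths with financial-year bed-days carry a
`year_basis_mismatch` flag; reconciling year bases is the caller's
responsibility.

## Mortality volatility

A rolling 12-month total always contains all four seasons, so any purely
12-periodic component cancels exactly. `adjacent_12m_diff_pct` compares
each 12-month block with the immediately preceding non-overlapping block
(April 2021–March 2022 against April 2020–March 2021): after an epidemic
year the differences turn negative. Quantiles of these differences across
areas (default quartiles) summarise how unevenly mortality shocks land.

The yardstick for "how much volatility is just counting noise" is the
Poisson standard deviation `100/√n` percent for an area with `n` annual
deaths: 3.2% at 1000, 2.6% at 1500. For the adjacent-block difference of
two independent Poisson year-totals with monthly mean `m`, the delta method
gives SD ≈ `100·√2/√(12m)` percent, which the simulated null reproduces.

Numerical conventions: quantiles use linear interpolation between order
statistics (the type-7 rule; no convention is canonical for this statistic,
so the choice is documented here). Windows are anchored to the calendar
months as given; the first 11 (and for differences, 23) months are dropped,
never padded. Differences with a zero earlier block are emitted as missing
and excluded from quantiles, with the exclusion count reported.

## Synthetic data

No public deposit covers the three input kinds, so seeded generators stand
in for them. Each unit (region or area) draws from its own RNG stream keyed
by `(seed, index)`, so enlarging a dataset never reshuffles existing units,
and every generator is a pure function of its config. Noise is
multiplicative everywhere — the generated quantities are positive,
scale-covariant rates.

* **Regions**: `x` uniform over a range, `y` on a chosen equivalence line
  times `1 + ε`, `ε ~ N(0, noise_sd)`; population, deaths and bed-days are
  back-solved so re-deriving the ratios reproduces `(x, y)` exactly.
  Counts are therefore real-valued, which the record types accept.
* **Subgroup panels**: per region, a log-uniform total population
  (150k–6M; jurisdiction sizes span orders of magnitude), a first-group
  share uniform on 0.02–0.35, per-group crude death rates varied per region
  (factors 0.6–2.0 and 0.7–1.4 around 7.0 and 6.5 per 1000), totals from
  the generating rates plus noise. The death-rate spread is deliberately at
  the wide end of what demography allows: the panel exists to exercise rate
  recovery, and without per-region rate variation the design is singular.
  Even so, with noise on regional totals the per-death rates are the
  weakly identified directions — their sampling error under a few percent
  of total noise is tens of percent at 8 regions, which is an honest
  property of the inference problem, not of the optimizer (the tests
  demonstrate it at the global optimum too).
* **Monthly deaths**: Poisson counts around a sinusoidal seasonal mean
  (default 125/month ≈ 1500/year, a median UK local-authority area;
  amplitude 0.15 peaking in January), with optional multiplicative
  outbreak windows, plus a deterministic-means mode that returns the
  expectations themselves for exact analytic window totals.

What passing tests on these data do *not* show: real panels carry model
misfit (the two-component linear decomposition is itself an
approximation), fiscal/calendar year mismatches, and undercounting that no
multiplicative noise term emulates; and real monthly death series are
overdispersed relative to Poisson, so real-world quartile bands are wider
than the simulated null's. The generators target the models' structure and
orders of magnitude, not real marginal distributions.

## Problem sizes

Defaults used in the test suite and the acceptance script: 50–200 regions
for line fitting; 8-region panels for the decomposition (matching a
states-of-a-federation use case); 800–2000 simulated areas × 24 months for
the volatility null. These sizes give Monte-Carlo errors comfortably inside
the assertion tolerances (e.g. the SD check at 2000 areas has ~1.6%
relative Monte-Carlo error against a 7% tolerance).

## Known limitations

* The log-linear form is empirical; other functional forms could fit
  comparably well, and the method works best for large areas — small-area
  demand mixes in birth- and age-driven care.
* Deviation scoring with available rather than occupied beds conflates
  provision with the occupancy margin, which depends strongly on hospital
  size; occupied beds are the meaningful demand measure.
* The decomposition reports point estimates only — no bootstrap intervals
  — and its per-death rates are intrinsically hard to pin down from few
  regions when noise enters at the level of regional totals (see above).
* The CLI's optional scatter plot is intentionally absent; the package
  emits tidy tables meant for downstream plotting.
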