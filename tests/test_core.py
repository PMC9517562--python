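"""Ratio construction, equivalence lines, deviation scoring and fits."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import bedbench as bb

# ---------------------------------------------------------------------------
# Ratios and unit conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "deaths, population, expected",
    [
        (4_500, 1_000_000, 4.5),
        (0, 1_000, 0.0),
        # England-scale consistency: an ageing population of ~56M with
        # ~498k deaths sits at 8.9 deaths per 1000 population.
        (498_400, 56_000_000, 8.9),
    ],
)
def test_crude_mortality_rate(deaths, population, expected):
    rec = bb.RegionRecord("r", "2019", population=population, deaths=deaths)
    assert bb.deaths_per_1000_population(rec) == pytest.approx(expected)


def test_crude_mortality_requires_positive_population():
    with pytest.raises(bb.InvalidInputError):
        bb.RegionRecord("r", "2019", population=0, deaths=0)


@pytest.mark.parametrize(
    "beds, deaths, expected",
    [(413, 100_000, 4.13), (3_200, 8_000, 400.0), (0, 5_000, 0.0)],
)
def test_beds_per_1000_deaths(beds, deaths, expected):
    assert bb.beds_per_1000_deaths(beds, deaths) == pytest.approx(expected)


def test_beds_per_1000_deaths_zero_deaths_is_undefined():
    with pytest.raises(bb.UndefinedRatioError):
        bb.beds_per_1000_deaths(100, 0)


@given(
    beds=st.floats(0, 1e6),
    deaths=st.floats(1, 1e6),
    population=st.floats(1e3, 1e8),
)
@settings(max_examples=200, deadline=None)
def test_beds_ratio_two_route_equality(beds, deaths, population):
    """Direct division equals the quotient of the two per-1000-pop rates."""
    direct = bb.beds_per_1000_deaths(beds, deaths)
    via_rates = 1000.0 * (1000.0 * beds / population) / (
        1000.0 * deaths / population
    )
    assert direct == pytest.approx(via_rates, rel=1e-12)


@pytest.mark.parametrize(
    "bed_days, expected, places",
    [
        (1509, 4.13, 2),   # bed-days per 1000 deaths -> occupied beds
        (365, 1.0, 12),
        (15, 0.041, 3),    # bed-days per 1000 population -> occupied beds
    ],
)
def test_occupied_beds_from_bed_days(bed_days, expected, places):
    assert round(bb.occupied_beds_from_bed_days(bed_days), places) == expected


@pytest.mark.parametrize(
    "bed_days, same_day, expected",
    [(1000, 100, 1035.0), (500, 0, 500.0), (0, 1000, 350.0)],
)
def test_same_day_adjustment(bed_days, same_day, expected):
    assert bb.adjust_for_same_day(bed_days, same_day) == pytest.approx(expected)


def test_same_day_adjustment_rejects_negative_inputs():
    with pytest.raises(bb.InvalidInputError):
        bb.adjust_for_same_day(-1, 0)
    with pytest.raises(bb.InvalidInputError):
        bb.adjust_for_same_day(0, -1)


@pytest.mark.parametrize(
    "births, deaths, expected", [(2500, 1000, 2.5), (0, 10, 0.0), (1000, 1000, 1.0)]
)
def test_births_per_death(births, deaths, expected):
    assert bb.births_per_death(births, deaths) == pytest.approx(expected)


def test_births_per_death_zero_deaths():
    with pytest.raises(bb.UndefinedRatioError):
        bb.births_per_death(100, 0)


# ---------------------------------------------------------------------------
# Slope-intercept relation and equivalence lines
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "intercept, expected",
    [
        (0.0, 0.0),
        (800.0, -228.97216),       # 0.000008756*640000 - 0.29322*800
        (640.0, -184.0743424),     # 0.000008756*409600 - 0.29322*640
    ],
)
def test_slope_from_intercept(intercept, expected):
    assert bb.slope_from_intercept(intercept) == pytest.approx(
        expected, abs=1e-9
    )


def test_slope_negative_over_working_interval():
    rel = bb.DEFAULT_RELATION
    upper = rel.max_negative_slope_intercept
    for a in (1.0, 100.0, 640.0, 2000.0, 20000.0, upper * 0.999):
        assert bb.slope_from_intercept(a) < 0
    assert bb.slope_from_intercept(upper * 1.001) > 0


def test_equivalence_value_examples(line_800):
    assert bb.equivalence_value(line_800, 1.0) == pytest.approx(800.0)
    assert bb.equivalence_value(line_800, math.e) == pytest.approx(
        800.0 + bb.slope_from_intercept(800.0)
    )
    # 800 - 228.97216 * ln(4.5)
    assert bb.equivalence_value(line_800, 4.5) == pytest.approx(
        455.608, abs=5e-3
    )


def test_equivalence_value_domain(line_800):
    with pytest.raises(bb.DomainError):
        bb.equivalence_value(line_800, 0.0)
    with pytest.raises(bb.DomainError):
        bb.equivalence_value(line_800, -1.0)


@given(a=st.floats(1.0, 5000.0))
@settings(max_examples=100, deadline=None)
def test_intercept_anchoring(a):
    """Every line passes through its intercept at x = 1."""
    line = bb.EquivalenceLine.from_intercept(a)
    assert bb.equivalence_value(line, 1.0) == pytest.approx(a, rel=1e-12)


@given(
    a=st.floats(10.0, 30000.0),
    x1=st.floats(0.1, 50.0),
    x2=st.floats(0.1, 50.0),
)
@settings(max_examples=200, deadline=None)
def test_lines_decline_with_crude_mortality(a, x1, x2):
    """Below the slope-sign boundary, equivalence values strictly decrease
    in deaths per 1000 population."""
    line = bb.EquivalenceLine.from_intercept(a)
    lo, hi = min(x1, x2), max(x1, x2)
    if hi / lo - 1.0 < 1e-9:  # below float resolution of ln
        return
    assert bb.equivalence_value(line, lo) > bb.equivalence_value(line, hi)


def test_deviation_pct_basics(line_800):
    y = bb.equivalence_value(line_800, 4.5)
    assert bb.deviation_pct(y, line_800, 4.5) == pytest.approx(0.0, abs=1e-12)
    assert bb.deviation_pct(2 * y, line_800, 4.5) == pytest.approx(100.0)
    # A jurisdiction at 4.5 deaths/1000 pop with 848 occupied beds per 1000
    # deaths sits ~86% above the intercept-800 line.
    assert bb.deviation_pct(848.0, line_800, 4.5) == pytest.approx(
        86.1, abs=0.05
    )


def test_deviation_sign_convention(line_800):
    y = bb.equivalence_value(line_800, 8.0)
    assert bb.deviation_pct(0.78 * y, line_800, 8.0) == pytest.approx(-22.0)


def test_deviation_degenerate_line(line_800):
    # Far enough right the intercept-800 line goes negative (x > e^(a/-b)).
    x_zero = math.exp(line_800.intercept / -line_800.slope)
    with pytest.raises(bb.DegenerateLineError):
        bb.deviation_pct(100.0, line_800, x_zero * 1.5)


# ---------------------------------------------------------------------------
# Intercept inversion
# ---------------------------------------------------------------------------


def _implied_intercept_bruteforce(x, y, relation=bb.DEFAULT_RELATION):
    """Independent oracle: bracket the root of a -> value(a, x) - y on a
    dense grid over (0, -c1/c2), then bisect."""
    upper = relation.max_negative_slope_intercept

    def f(a):
        line = bb.EquivalenceLine.from_intercept(a, relation)
        return bb.equivalence_value(line, x) - y

    grid = np.linspace(1e-6, upper - 1e-6, 20000)
    vals = np.array([f(a) for a in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    assert len(sign_changes) == 1, "oracle expects a unique admissible root"
    lo, hi = grid[sign_changes[0]], grid[sign_changes[0] + 1]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def test_implied_intercept_at_x_equal_one():
    assert bb.implied_intercept(1.0, 750.0) == pytest.approx(750.0, rel=1e-12)


def test_implied_intercept_round_trip(line_800):
    y = bb.equivalence_value(line_800, 4.5)
    assert bb.implied_intercept(4.5, y) == pytest.approx(800.0, rel=1e-9)


@pytest.mark.parametrize("x, y", [(0.5, 900.0), (2.5, 600.0), (12.0, 300.0)])
def test_implied_intercept_matches_bracketing_oracle(x, y):
    a = bb.implied_intercept(x, y)
    a_oracle = _implied_intercept_bruteforce(x, y)
    assert a == pytest.approx(a_oracle, rel=1e-6)
    line = bb.EquivalenceLine.from_intercept(a)
    assert bb.equivalence_value(line, x) == pytest.approx(y, rel=1e-9)


@given(a=st.floats(100.0, 2000.0), x=st.floats(2.0, 15.0))
@settings(max_examples=300, deadline=None)
def test_implied_intercept_inverse_consistency(a, x):
    line = bb.EquivalenceLine.from_intercept(a)
    y = bb.equivalence_value(line, x)
    if y <= 0:
        return
    assert bb.implied_intercept(x, y) == pytest.approx(a, rel=1e-9)


def test_implied_intercept_rejects_bad_inputs():
    with pytest.raises(bb.DomainError):
        bb.implied_intercept(0.0, 500.0)
    with pytest.raises(bb.InvalidInputError):
        bb.implied_intercept(4.0, -5.0)


# ---------------------------------------------------------------------------
# Occupied-bed prediction
# ---------------------------------------------------------------------------


def test_predict_occupied_beds_at_x_one(line_800):
    # D/P = 1/1000 puts the region at x = 1, where the line value is the
    # intercept, so beds = D * a.
    assert bb.predict_occupied_beds(1.0, 1000.0, line_800) == pytest.approx(
        800.0
    )


def test_predict_occupied_beds_composition(line_800):
    expected = 4.5 * bb.equivalence_value(line_800, 4.5)
    assert bb.predict_occupied_beds(4.5, 1000.0, line_800) == pytest.approx(
        expected, rel=1e-12
    )


@given(
    a=st.floats(100.0, 2000.0),
    d=st.floats(0.5, 500.0),
    ratio=st.floats(50.0, 400.0),
)
@settings(max_examples=200, deadline=None)
def test_predict_occupied_beds_folded_form_identity(a, d, ratio):
    """The rearranged D*[a' + b'*ln(P) - b'*ln(D)] form is the same number
    as the direct route through the equivalence value."""
    line = bb.EquivalenceLine.from_intercept(a)
    p = d * ratio
    direct = bb.predict_occupied_beds(d, p, line)
    folded = bb.predict_occupied_beds_folded(d, p, line)
    assert folded == pytest.approx(direct, rel=1e-12)


def test_predict_occupied_beds_homogeneity(line_800):
    one = bb.predict_occupied_beds(4.5, 1000.0, line_800)
    two = bb.predict_occupied_beds(9.0, 2000.0, line_800)
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_predict_occupied_beds_invalid_inputs(line_800):
    with pytest.raises(bb.InvalidInputError):
        bb.predict_occupied_beds(0.0, 100.0, line_800)
    with pytest.raises(bb.InvalidInputError):
        bb.predict_occupied_beds(200.0, 100.0, line_800)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_fit_loglinear_exact_recovery():
    line = bb.EquivalenceLine.from_intercept(640.0)
    pts = [
        bb.RatioPoint(x, bb.equivalence_value(line, x)) for x in (2.0, 5.0, 9.0)
    ]
    fit = bb.fit_loglinear(pts)
    assert fit.intercept == pytest.approx(640.0, abs=1e-9)
    assert fit.slope == pytest.approx(bb.slope_from_intercept(640.0), abs=1e-9)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)


def test_fit_loglinear_two_points_interpolates():
    pts = [bb.RatioPoint(2.0, 700.0), bb.RatioPoint(8.0, 400.0)]
    fit = bb.fit_loglinear(pts)
    for p in pts:
        assert (
            fit.intercept + fit.slope * math.log(p.deaths_per_1000_pop)
        ) == pytest.approx(p.beds_per_1000_deaths, rel=1e-12)


def test_fit_loglinear_noisy_recovery_within_3se():
    rng = np.random.default_rng(42)
    line = bb.EquivalenceLine.from_intercept(640.0)
    xs = rng.uniform(3.0, 12.0, size=50)
    pts = [
        bb.RatioPoint(
            x, bb.equivalence_value(line, x) * (1 + rng.normal(0, 0.02))
        )
        for x in xs
    ]
    fit = bb.fit_loglinear(pts)
    assert abs(fit.intercept - 640.0) < 3 * fit.intercept_se
    assert abs(fit.slope - line.slope) < 3 * fit.slope_se


def test_fit_loglinear_underdetermined():
    with pytest.raises(bb.UnderdeterminedError):
        bb.fit_loglinear([bb.RatioPoint(4.0, 500.0)])
    with pytest.raises(bb.UnderdeterminedError):
        bb.fit_loglinear([bb.RatioPoint(4.0, 500.0), bb.RatioPoint(4.0, 600.0)])


def test_fit_slope_intercept_relation_exact():
    pairs = [(a, bb.slope_from_intercept(a)) for a in (200.0, 500.0, 800.0, 1100.0)]
    rel = bb.fit_slope_intercept_relation(pairs)
    assert rel.c2 == pytest.approx(0.000008756, abs=1e-9)
    assert rel.c1 == pytest.approx(-0.29322, abs=1e-9)


def test_fit_slope_intercept_relation_two_pairs_exact_solve():
    pairs = [(300.0, -80.0), (900.0, -250.0)]
    rel = bb.fit_slope_intercept_relation(pairs)
    for a, b in pairs:
        assert rel.c2 * a**2 + rel.c1 * a == pytest.approx(b, rel=1e-10)


def test_fit_slope_intercept_relation_noisy_within_3se():
    rng = np.random.default_rng(7)
    a = rng.uniform(150.0, 1600.0, size=20)
    b = np.array([bb.slope_from_intercept(ai) for ai in a]) + rng.normal(
        0.0, 1.0, size=20
    )
    rel = bb.fit_slope_intercept_relation(list(zip(a, b)))
    # Independent route: statsmodels no-constant OLS supplies the SEs.
    res = sm.OLS(b, np.column_stack([a**2, a])).fit()
    assert rel.c2 == pytest.approx(res.params[0], rel=1e-10)
    assert rel.c1 == pytest.approx(res.params[1], rel=1e-10)
    assert abs(rel.c2 - 0.000008756) < 3 * res.bse[0]
    assert abs(rel.c1 - (-0.29322)) < 3 * res.bse[1]


def test_fit_slope_intercept_relation_through_origin():
    rel = bb.fit_slope_intercept_relation(
        [(a, bb.slope_from_intercept(a)) for a in (250.0, 750.0, 1250.0)]
    )
    assert bb.slope_from_intercept(0.0, rel) == 0.0


# ---------------------------------------------------------------------------
# Region pipeline
# ---------------------------------------------------------------------------


def test_benchmark_regions_excludes_zero_death_regions(line_800):
    y = bb.equivalence_value(line_800, 4.5)
    good = bb.RegionRecord(
        "good", "2019", population=1_000_000, deaths=4_500,
        occupied_bed_days=y * 4.5 * 365.0,
    )
    dead_quiet = bb.RegionRecord(
        "no-deaths", "2019", population=50_000, deaths=0,
        occupied_bed_days=1000.0,
    )
    table, excluded = bb.benchmark_regions([good, dead_quiet], [800.0])
    assert excluded == ["no-deaths"]
    assert list(table["region_id"]) == ["good"]
    assert table["deviation_pct"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert table["implied_intercept"].iloc[0] == pytest.approx(800.0, rel=1e-9)


def test_region_ratio_point_applies_same_day_and_conversion():
    rec = bb.RegionRecord(
        "r", "2019", population=1_000_000, deaths=8_000,
        occupied_bed_days=1_000_000.0, same_day_admissions=100_000.0,
    )
    pt = bb.region_ratio_point(rec)
    beds = (1_000_000.0 + 0.35 * 100_000.0) / 365.0
    assert pt.beds_per_1000_deaths == pytest.approx(1000 * beds / 8000, rel=1e-12)
    assert pt.deaths_per_1000_pop == pytest.approx(8.0)
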