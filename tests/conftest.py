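import pytest

from bedbench import EquivalenceLine, SubgroupRates


@pytest.fixture
def line_800() -> EquivalenceLine:
    """Reference line: 800 beds per 1000 deaths at 1 death per 1000 pop."""
    return EquivalenceLine.from_intercept(800.0)


@pytest.fixture
def indigenous_truth() -> SubgroupRates:
    """The generating decomposition rates, per-population rate of the
    majority group held fixed."""
    return SubgroupRates(
        groups=("indigenous", "non_indigenous"),
        per_1000_deaths=(1509.0, 429.0),
        per_1000_population=(90.0, 15.0),
        fixed_per_1000_population=(False, True),
    )


@pytest.fixture
def decomposition_init() -> SubgroupRates:
    """Neutral starting point with the majority per-population rate fixed."""
    return SubgroupRates(
        groups=("indigenous", "non_indigenous"),
        per_1000_deaths=(100.0, 100.0),
        per_1000_population=(100.0, 15.0),
        fixed_per_1000_population=(False, True),
    )


def months_from(start_year: int, n: int) -> list[str]:
    """n contiguous YYYY-MM labels starting January of start_year."""
    out = []
    year, month = start_year, 1
    for _ in range(n):
        out.append(f"{year}-{month:02d}")
        month += 1
        if month == 13:
            year, month = year + 1, 1
    return out
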