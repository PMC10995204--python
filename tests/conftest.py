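import numpy as np
import pytest

from sullivan_hle import (
    AgeGrid,
    MortalitySchedule,
    build_life_table,
    fixture_path,
    read_prevalence_csv,
)
from sullivan_hle.pipeline import extend_prevalence_young_ages
from sullivan_hle.synthetic import SyntheticScenario, generate_mortality


@pytest.fixture(scope="session")
def grid():
    return AgeGrid.default()


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario()


@pytest.fixture(scope="session")
def total_lifetable(scenario):
    return build_life_table(generate_mortality(scenario, sex="total"))


@pytest.fixture(scope="session")
def table1_total(grid):
    """Published total-population prevalence schedules, extended to birth."""
    scheds = read_prevalence_csv(fixture_path("table1_prevalence.csv"))
    return {
        s.condition: extend_prevalence_young_ages(s, grid)
        for s in scheds
        if s.stratum.sex == "total"
    }


def random_mortality(rng, grid):
    """A plausible random mortality schedule: rising adult rates, infant bump."""
    k = len(grid)
    base = np.sort(rng.uniform(0.0005, 0.05, size=k))
    base[0] += rng.uniform(0.0, 0.04)
    base[-1] = rng.uniform(0.08, 0.3)
    return MortalitySchedule(grid=grid, mx=base)


def naive_sullivan(lt, pi):
    """Independent double-loop evaluation of the Sullivan sum."""
    k = len(lt.grid)
    out = np.empty(k)
    for x in range(k):
        acc = 0.0
        for i in range(x, k):
            acc += lt.Lx[i] * (1.0 - pi[i])
        out[x] = acc / lt.lx[x]
    return out
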