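"""Sullivan-method health expectancy from abridged period life tables."""

from importlib.resources import files

from .comorbidity import (
    BOTH,
    CONDITIONS,
    DIABETES,
    EITHER,
    HYPERTENSION,
    ConditionSet,
    derive_combined,
    validate_condition_set,
)
from .grids import OPEN, AgeGrid, Stratum
from .lifetable import (
    AxMode,
    LifeTable,
    MortalitySchedule,
    SeparationFactor,
    build_life_table,
    qx_from_mx,
    read_mortality_csv,
    write_life_table_csv,
)
from .pipeline import (
    StudyConfig,
    StudyResult,
    extend_prevalence_young_ages,
    run_study,
)
from .sullivan import (
    DifferenceTest,
    HealthExpectancyTable,
    PrevalenceSchedule,
    ci,
    difference_test,
    health_expectancy,
    hle_variance,
    read_prevalence_csv,
)
from .synthetic import (
    LogisticPrevalence,
    MicrosimResult,
    SyntheticScenario,
    bgd2018_like,
    generate_mortality,
    generate_prevalence,
    microsim_hle,
    sample_survey,
)

__version__ = "0.1.0"


def fixture_path(name: str):
    """Path to a packaged data fixture (e.g. 'table1_prevalence.csv')."""
    return files("sullivan_hle").joinpath("fixtures", name)
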