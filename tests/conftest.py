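import numpy as np
import pytest

from gpselect import (
    GeneratorParams,
    ImputationConfig,
    LinkedCohort,
    apply_historical_selection,
    generate_cohort,
    impute,
)

#: Small-but-structured cohort used across modules: 2 years x 1500 applicants.
SMALL_PARAMS = GeneratorParams(n_per_year=1500, n_years=2, n_appointed_per_year=700)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """(masked cohort, truth table, complete applications frame)."""
    apps, truth = generate_cohort(small_params, seed=11)
    cohort = apply_historical_selection(apps, truth, small_params)
    return cohort, truth, apps


@pytest.fixture(scope="session")
def small_imputations(small_cohort):
    cohort, _, _ = small_cohort
    return impute(cohort, ImputationConfig(m=4, n_iterations=4, seed=77))


@pytest.fixture(scope="session")
def complete_dataset(small_cohort):
    """The same cohort with nothing missing (built from the generator truth)."""
    _, _, apps = small_cohort
    return LinkedCohort(apps.copy())


@pytest.fixture(scope="session")
def table4():
    from gpselect import load_table4

    return load_table4()


def toy_dataset(rows):
    """Completed dataset from a list of dicts with sensible defaults."""
    import pandas as pd

    defaults = dict(
        gmc_id="G", year=2011, round="R1", cps_score=250.0, pd_score=250.0,
        stage3_total=80.0, stage3_competent=1.0, withdrew=0.0, offer_accepted=1.0,
        ltft=0.0, oop=0.0, arcp4=0.0, fte_months=36.0, gender="F",
        ethnicity_bme=0.0, uk_pmq=1.0,
    )
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    frame["stage2_total"] = frame["cps_score"] + frame["pd_score"]
    return LinkedCohort(frame)
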