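"""Shared fixtures: calibrated generative parameter sets and small cohorts.

Expensive artefacts (calibrated baseline rates, mid-size simulated cohorts)
are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pandas as pd
import pytest

from jointsnp.cohort import CohortData
from jointsnp.simulate import (ScenarioSpec, calibrate_lambda, simulate_cohort,
                               table1_defaults)


@pytest.fixture(scope="session")
def base_params():
    """Reference generative parameters, uncalibrated."""
    return table1_defaults()


@pytest.fixture(scope="session")
def params_d0384(base_params):
    """Reference parameters with the baseline rate calibrated to 3.84%."""
    return base_params.with_lambda(calibrate_lambda(base_params, 0.0384))


@pytest.fixture(scope="session")
def params_d10(base_params):
    """Reference parameters calibrated to 10% incidence (event-rich, used
    where tests need enough events at small n)."""
    return base_params.with_lambda(calibrate_lambda(base_params, 0.1))


@pytest.fixture(scope="session")
def small_cohort(params_d10):
    """One simulated cohort of n=400 at 10% incidence, with truth."""
    spec = ScenarioSpec(m=4, n=400, f=0.244, d=0.1, base_seed=20260901)
    return simulate_cohort(spec, params_d10, replicate=0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Hand-written three-individual cohort for exact-value tests."""
    longitudinal = pd.DataFrame({
        "id": [1, 1, 2, 2, 3, 3],
        "time": [0.0, 3.0, 0.0, 3.0, 0.0, 6.0],
        "value": [4.2, 4.5, 5.1, 5.3, 4.8, 4.6],
    })
    survival = pd.DataFrame({
        "id": [1, 2, 3],
        "time": [5.0, 4.0, 9.0],
        "status": [1, 1, 0],
    })
    return CohortData(longitudinal, survival)


def make_cohort(longitudinal_rows, survival_rows):
    """Build a CohortData from (id, time, value) and (id, time, status)."""
    lon = pd.DataFrame(longitudinal_rows, columns=["id", "time", "value"])
    surv = pd.DataFrame(survival_rows, columns=["id", "time", "status"])
    return CohortData(lon, surv)
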