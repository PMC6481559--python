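import numpy as np
import pandas as pd
import pytest

from cohortmi.designs import sample_case_cohort, sample_ncc, cc_risk_sets
from cohortmi.harness import StudyConfig, prepare_replicate, standard_scenario
from cohortmi.simulate import SimScenario, simulate_cohort


def make_cohort(times, events, **covs) -> pd.DataFrame:
    """Small hand-built cohort table."""
    n = len(times)
    df = pd.DataFrame({"id": np.arange(n), "time": times, "event": events})
    for name, vals in covs.items():
        df[name] = vals
    df["miss_x1_design"] = 0
    df["miss_x2_chance"] = 0
    return df


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    return standard_scenario(effect=0.2, missing_frac=0.5, n_cohort=2000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_scenario) -> pd.DataFrame:
    return simulate_cohort(small_scenario)


@pytest.fixture(scope="session")
def cc_replicate(small_scenario):
    cfg = StudyConfig(design="cc", n_subcohort=300)
    return prepare_replicate(small_scenario, cfg, np.random.SeedSequence(5)), cfg


@pytest.fixture(scope="session")
def ncc_replicate(small_scenario):
    cfg = StudyConfig(design="ncc", c_per_case=1)
    return prepare_replicate(small_scenario, cfg, np.random.SeedSequence(6)), cfg
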