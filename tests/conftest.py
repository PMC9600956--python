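import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from owhto import CohortSpec, generate_cohort, make_leg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from owhto.experiment import run_conditions


@pytest.fixture
def mean_leg():
    """6 degree varus limb with the cohort-mean geometry."""
    return make_leg(varus_angle=6.0, femoral_length=475.0,
                    tibial_length=372.6, plateau_width=79.5)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def wedge_table(default_cohort):
    return run_conditions(default_cohort)


@pytest.fixture(scope="session")
def multi_seed_tables():
    """Wedge tables for 20 independent default cohorts (seeds 100..119)."""
    out = []
    for seed in range(100, 120):
        cohort = generate_cohort(CohortSpec(seed=seed))
        out.append((cohort, run_conditions(cohort)))
    return out


def wide_wedges(table: pd.DataFrame) -> pd.DataFrame:
    ok = table[table["status"] == "ok"]
    return ok.pivot(index="knee_id", columns="condition", values="wedge_mm")
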