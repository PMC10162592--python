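import logging

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rxoutliers import orgs, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# keep filter-stage INFO chatter out of test output
logging.getLogger("rxoutliers").setLevel(logging.WARNING)


@pytest.fixture()
def register_df() -> pd.DataFrame:
    rows = [
        ("P1", "Alpha Surgery", "practice", "True"),
        ("P2", "Beta Surgery", "practice", "True"),
        ("P3", "Gamma Prison Clinic", "practice", "False"),
        ("P4", "Delta Surgery", "practice", "True"),
        ("PCN1", "Network 1", "pcn", ""),
        ("CCG1", "Group 1", "ccg", ""),
        ("CCG2", "Group 2", "ccg", ""),
        ("STP1", "Partnership 1", "stp", ""),
    ]
    return pd.DataFrame(rows, columns=["org_code", "name", "level", "is_typical"])


@pytest.fixture()
def mapping_df() -> pd.DataFrame:
    rows = [
        ("P1", "PCN1", "CCG1", "STP1"),
        ("P2", "PCN1", "CCG1", "STP1"),
        ("P3", "", "CCG2", "STP1"),
        ("P4", "", "CCG2", "STP1"),  # no PCN: orphan at that level
    ]
    return pd.DataFrame(
        rows, columns=["practice_code", "pcn_code", "ccg_code", "stp_code"]
    )


@pytest.fixture()
def hierarchy(register_df, mapping_df) -> orgs.OrgHierarchy:
    return orgs.load_hierarchy(register_df, mapping_df)


@pytest.fixture(scope="session")
def planted_dataset() -> simulate.SimulatedDataset:
    """One default synthetic extract with the canonical planted outlier."""
    cfg = simulate.default_config(seed=7, planted=(simulate.example_planted(),))
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def devon_matrix():
    return simulate.devon_fixture()
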