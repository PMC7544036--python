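import numpy as np
import pandas as pd
import pytest

from irgps import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def tiny_expression():
    """3 genes x 4 samples with a tie and a zero, hand-checkable."""
    return pd.DataFrame(
        {
            "s1": [5.0, 3.0, 0.0],
            "s2": [4.0, 4.0, 1.0],
            "s3": [1.0, 2.0, 7.0],
            "s4": [2.5, 2.5, 2.5],
        },
        index=pd.Index(["HFE", "SLPI", "KDR"], name="gene"),
    )


@pytest.fixture
def six_subject_survival():
    """Six subjects, one censored: the worked example for ROC/log-rank oracles."""
    return pd.DataFrame(
        {
            "os_time": [5.0, 10.0, 15.0, 20.0, 30.0, 40.0],
            "event": [1, 1, 0, 1, 1, 0],
        },
        index=pd.Index([f"p{i}" for i in range(1, 7)], name="sample_id"),
    )
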