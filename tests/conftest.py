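import numpy as np
import pytest

from gmlcs import SimConfig, generate_study
from gmlcs.data_hygiene import stack_standardize_all


@pytest.fixture(scope="session")
def study_table():
    """Study-sized synthetic table (35 + 40), one coupled ROI, with the
    default missingness process."""
    return generate_study(SimConfig(rois=("ACC_R",), seed=7))


@pytest.fixture(scope="session")
def complete_table():
    """Larger complete-data table (no dropout/MCAR) for engine tests."""
    cfg = SimConfig(
        n_per_group=150, rois=("ACC_R",), dropout_prob=0.0, mcar_rate=0.0, seed=11
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def standardized_table(complete_table):
    return stack_standardize_all(complete_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
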