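import numpy as np
import pytest

from nifhnet.synthetic import StudyDesign, generate_logs, generate_occurrences


@pytest.fixture(scope="session")
def study_logs():
    """Default-size (45 log) covariate table."""
    return generate_logs(StudyDesign(seed=3))


@pytest.fixture(scope="session")
def study_tables(study_logs):
    """(fungal, motu, truth) occurrence tables for the default study."""
    return generate_occurrences(study_logs, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
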