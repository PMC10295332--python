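import numpy as np
import pytest

from wnetecg import SyntheticSubjectConfig, generate_paired_record


@pytest.fixture(scope="session")
def short_record():
    """A 60-s synthetic subject used by fast tests (7500 samples at 125 Hz)."""
    cfg = SyntheticSubjectConfig(duration_s=60.0, seed=7)
    return generate_paired_record(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
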