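import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
    settings.load_profile("suite")
except ImportError:
    pass

from rdd_gxe.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest complete cohort around the cutoff for reuse across tests."""
    cfg = SyntheticConfig(
        n_subjects=2000,
        date_range=(-50, 50),
        pre_fraction=0.5,
        missing_rates={},
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
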