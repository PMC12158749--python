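import numpy as np
import pytest

from habitatus.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six compact paired cases for I/O and feature-contract tests."""
    cfg = SynthConfig(
        n_cases=6,
        image_size=(96, 96),
        lesion_axes_range=(12, 22),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def one_case(small_cohort):
    return small_cohort[0][0]


@pytest.fixture(scope="session")
def one_truth(small_cohort):
    return small_cohort[0][1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
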