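import numpy as np
import pytest

from ectau import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One default 10-case synthetic cohort, shared across read-only tests."""
    return synthetic.generate_cohort(synthetic.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_slide():
    """One fraction-driven synthetic section with ground truth."""
    return synthetic.generate_slide(synthetic.SlideSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
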