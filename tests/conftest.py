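import numpy as np
import pytest

import lesionhet as lh


@pytest.fixture(scope="session")
def cohort84() -> lh.Cohort:
    """A mid-sized cohort with planted signal in both feature blocks."""
    config = lh.SimulationConfig(n_train=60, n_test=24, seed=11)
    return lh.generate_cohort(config)


@pytest.fixture(scope="session")
def het84(cohort84) -> "pd.DataFrame":  # noqa: F821
    return lh.heterogeneity_table(cohort84.patients, lh.TextureConfig(seed=11))


@pytest.fixture(scope="session")
def tables84(cohort84):
    return {
        "clinical": cohort84.clinical_frame(),
        "lesions": lh.lesion_measurement_table(cohort84.patients),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
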