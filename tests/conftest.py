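import numpy as np
import pytest

from osahrv.osa_classifier import build_feature_table
from osahrv.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 4x8 cohort shared by the classifier and pipeline tests."""
    return generate_cohort(CohortSpec(n_per_class=8, seed=11, artifact_rate=0.005))


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    table, exclusions = build_feature_table(small_cohort)
    assert len(table) + len(exclusions) == len(small_cohort)
    return table


def random_rri(seed: int, n: int, mean: float = 850.0, sd: float = 40.0) -> np.ndarray:
    """A positive i.i.d. Gaussian RR series used across oracle tests."""
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(mean, sd, n), 300.0, None)
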