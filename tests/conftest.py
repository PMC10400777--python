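import numpy as np
import pytest

from scn_cpm.atlas_io import CohortGMV


def make_cohort(n_subjects: int, n_regions: int, seed: int) -> CohortGMV:
    """An unstructured random cohort (independent Gaussian regions)."""
    rng = np.random.default_rng(seed)
    return CohortGMV(
        subject_ids=[f"S{i:03d}" for i in range(n_subjects)],
        gmv=rng.normal(500.0, 20.0, (n_subjects, n_regions)),
        score=rng.uniform(0.0, 10.0, n_subjects),
    )


@pytest.fixture
def random_cohort():
    return make_cohort


@pytest.fixture
def small_cohort():
    return make_cohort(12, 5, seed=42)
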