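import numpy as np
import pytest

from vocalfold.features import compute_feature_table
from vocalfold.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-pig cohort (3 PRE + 3 POST_EARLY dates, 8 squeals/day) with its
    feature table; shared across tests because synthesis dominates runtime."""
    spec = CohortSpec(
        pig_ids=("pig_a", "pig_b"),
        recording_days=(-30, -20, -10, 3, 8, 13),
        squeals_per_day=8,
        seed=11,
    )
    recordings, labels = generate_cohort(spec)
    table = compute_feature_table(recordings, labels)
    return spec, recordings, labels, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
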