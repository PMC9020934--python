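import numpy as np
import pytest

from obefs import FeatureTable, SyntheticSpec, generate_synthetic


@pytest.fixture
def toy_table() -> FeatureTable:
    """2 subjects x 3 recordings, 4 features, cleanly separable on feature 0."""
    rng = np.random.default_rng(0)
    values = rng.standard_normal((6, 4))
    values[:3, 0] -= 4.0
    values[3:, 0] += 4.0
    return FeatureTable(
        values=values,
        subject_id=np.array([1, 1, 1, 2, 2, 2]),
        label=np.array([0, 0, 0, 1, 1, 1]),
        feature_names=["f0", "f1", "f2", "f3"],
        feature_family=["mfcc", "mfcc", "tqwt", "tqwt"],
    )


@pytest.fixture
def separable_table() -> FeatureTable:
    """20 subjects, strong class shift on 2 of 6 features."""
    table, _ = generate_synthetic(
        SyntheticSpec(
            n_subjects_per_class=10,
            n_informative=2,
            n_redundant=1,
            n_noise=3,
            effect_size=3.0,
            seed=5,
        )
    )
    return table


@pytest.fixture
def small_noisy_table():
    """Small table with known informative/redundant/noise split."""
    return generate_synthetic(
        SyntheticSpec(
            n_subjects_per_class=12,
            n_informative=3,
            n_redundant=2,
            n_noise=10,
            effect_size=2.0,
            seed=9,
        )
    )
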