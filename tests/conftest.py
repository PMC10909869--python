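import numpy as np
import pytest

from neurofuse.synth import (
    EffectSpec,
    TimelineParams,
    default_mri_spec,
    default_pet_spec,
    make_toy_atlas,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def atlas():
    return make_toy_atlas((32, 32, 32), 10, seed=0)


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """A compact labelled cohort reused by cohort/split tests."""
    records, events = simulate_cohort(
        n_subjects=12,
        prevalence=0.5,
        atlas=atlas,
        mri_spec=default_mri_spec(),
        pet_spec=default_pet_spec(),
        timeline_params=TimelineParams(n_visits=3, flip_prob=0.1),
        seed=7,
    )
    return records, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
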