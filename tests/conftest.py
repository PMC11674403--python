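import numpy as np
import pytest

from twinstates import default_base_model, generate_cohort
from twinstates.synth import AceSpec, CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    model = default_base_model(K=3, R=6, seed=7)
    model.validate()
    return model


@pytest.fixture(scope="session")
def mini_cohort():
    """A small heritable cohort shared across feature/heritability tests."""
    config = CohortConfig(
        n_mz_pairs=6,
        n_dz_pairs=4,
        n_ur_pairs=4,
        n_regions=6,
        n_states=3,
        duration_s=40.0,
        seed=11,
        effect_scale=1.5,
    )
    spec = AceSpec(a2=0.6, e2=0.4)
    manifest, envelopes, truth = generate_cohort(config, spec)
    return config, spec, manifest, envelopes, truth
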