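import numpy as np
import pytest
from hypothesis import settings

from traitscape.synthdata import SimConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def tiny_config(**overrides) -> SimConfig:
    """A minutes-scale-down cohort: 216 voxels, 20 regions, 60 subjects."""
    base = dict(
        n_subjects=60,
        n_trials_neg=8,
        n_trials_neu=8,
        grid_shape=(6, 6, 6),
        n_regions=20,
        n_networks=7,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the documented default study conditions."""
    return generate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
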