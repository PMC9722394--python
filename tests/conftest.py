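import numpy as np
import pytest
from hypothesis import settings

from nirsfc.montage import load_montage
from nirsfc.simulate import CohortSpec, NuisanceSpec, default_calibration

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return load_montage()


@pytest.fixture(scope="session")
def tiny_spec(montage):
    """A fast cohort: 3 subjects per group, 2 minutes of data."""
    return default_calibration(seed=7, n_per_group=3, duration=120.0,
                               montage=montage)


def quiet_spec(montage, **overrides) -> CohortSpec:
    """A noise-free, artifact-free spec for forward/inverse oracles."""
    kw = dict(
        n_per_group=2, duration=120.0, montage=montage,
        nuisance=NuisanceSpec(cardiac_amp=0, resp_amp=0, mayer_amp=0),
        drift_od=0.0, sensor_noise_sd=0.0, artifact_rate=0.0, seed=3,
    )
    kw.update(overrides)
    return default_calibration(**kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
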