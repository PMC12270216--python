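import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A 6-region truth spec (4 subcortical + 2 cortical) for fast tests."""
    from lifetraj.synth import TruthSpec

    spec = TruthSpec(seed=11)
    spec.rois = spec.rois[:4] + spec.rois[10:12]
    return spec


@pytest.fixture(scope="session")
def small_cohorts(small_spec):
    from lifetraj.synth import generate_cohorts

    return generate_cohorts(small_spec, 300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
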