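import pytest
from hypothesis import HealthCheck, settings

from glycoatlas.synthetic import SyntheticAtlasSpec, generate_atlas

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def atlas():
    """Full-size synthetic atlas: 18 classes x 5 replicates x 103 glycoforms."""
    return generate_atlas(SyntheticAtlasSpec(seed=7))


@pytest.fixture(scope="session")
def small_atlas():
    """Small atlas for fast unit tests: 4 classes x 5 replicates x 20 glycoforms."""
    spec = SyntheticAtlasSpec(
        n_classes=4, replicates=5, library_size=20, marker_count=3, seed=11
    )
    return generate_atlas(spec)
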