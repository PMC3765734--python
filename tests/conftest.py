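import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    from dgetag.simulate import SimulationConfig

    return SimulationConfig(
        n_transcripts=60,
        transcript_length_range=(120, 400),
        depth_per_library=5_000,
        seed=7,
    )


def random_tag(rng, length=17):
    return "".join(rng.choice(list("ACGT"), size=length))
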