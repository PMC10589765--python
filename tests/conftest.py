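import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormsynth.detector import detect
from wormsynth.pipeline import EASY_DETECTOR, GenerationConfig, generate_scenes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: root seed for the shared easy-condition dataset fixtures
EASY_SEED = 11


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def easy_scenes_200():
    """200 seeded easy-condition scenes, shared across the suite."""
    return generate_scenes(GenerationConfig(), 200, seed=EASY_SEED)


@pytest.fixture(scope="session")
def easy_detections_200(easy_scenes_200):
    """Baseline-detector output on the shared easy scenes."""
    return [detect(s.image, EASY_DETECTOR) for s in easy_scenes_200]
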