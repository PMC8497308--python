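import numpy as np
import pytest

from teevae.simulate import BubbleEvent, SceneParams, generate_scene


def small_params(seed: int = 3, duration_s: float = 45.0, **kw) -> SceneParams:
    """Compact scene parameters for fast unit tests."""
    defaults = dict(fps=38.0, duration_s=duration_s, width=160, height=120,
                    period_s=0.8, seed=seed)
    defaults.update(kw)
    return SceneParams(**defaults)


@pytest.fixture(scope="session")
def quiet_scene():
    """45 s bubble-free, artifact-free scene."""
    return generate_scene(small_params(seed=11))


@pytest.fixture(scope="session")
def event_scene():
    """60 s scene with one strong grade-3 event well after warm-up."""
    params = small_params(seed=7, duration_s=60.0)
    return generate_scene(params, [BubbleEvent(900, 1500, 3, bubble_rate=25.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
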