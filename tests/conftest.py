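import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mt_scene():
    """One default synthetic trichrome scene with a 30% collagen patch."""
    from fibroquant import MTSceneParams, generate_mt_image

    params = MTSceneParams(collagen_patch_fraction=0.30, seed=11)
    img, truth = generate_mt_image(params)
    return params, img, truth


@pytest.fixture(scope="session")
def if_scene():
    from fibroquant import IFSceneParams, generate_if_stack

    params = IFSceneParams(seed=5)
    stack, centers = generate_if_stack(params)
    return params, stack, centers


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
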