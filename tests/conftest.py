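import numpy as np
import pytest

from gqwaters import assign_roles
from gqwaters.synthetic import SceneSpec, generate_scene, scene_role_overrides


@pytest.fixture
def scene_factory():
    """Build a (structure, truth, roles) triple from SceneSpec kwargs."""

    def make(**kwargs):
        spec = SceneSpec(**kwargs)
        structure, truth = generate_scene(spec)
        roles = assign_roles(structure, scene_role_overrides())
        return structure, truth, roles

    return make


@pytest.fixture
def small_scene(scene_factory):
    return scene_factory(
        waters_per_bridge=2, n_bridges=2, n_decoy_waters=5, jitter_sd=0.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
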