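import numpy as np
import pytest

from martian import phantom_sim as sim


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def head_spec():
    """A structured metal-free head phantom spec used across tests."""
    return sim.PhantomSpec(
        image_size=64, seed=2,
        bone_structures=tuple(
            sim.BoneSpec(shape=sim.Shape(center=c, radii=r))
            for c, r in [((0.35, 0.35), (0.05, 0.04)),
                         ((0.62, 0.40), (0.04, 0.06)),
                         ((0.50, 0.62), (0.06, 0.04)),
                         ((0.40, 0.55), (0.03, 0.03)),
                         ((0.60, 0.60), (0.03, 0.05))]))


@pytest.fixture(scope="session")
def head_image(head_spec):
    return sim.render_anatomy(head_spec)


@pytest.fixture(scope="session")
def metal_spec():
    """Two metal inserts so beam hardening produces a dark band between them."""
    return sim.PhantomSpec(
        image_size=64, seed=3,
        metal_inserts=(sim.MetalSpec(center=(0.42, 0.45), radius=0.03, hu=4000.0),
                       sim.MetalSpec(center=(0.58, 0.45), radius=0.03, hu=4000.0)))


@pytest.fixture(scope="session")
def metal_image(metal_spec):
    return sim.render_anatomy(metal_spec)
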