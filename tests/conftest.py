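import sys
import pathlib

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from fundusreg.phantom import NoiseParams, PhantomSpec, generate_tree, \
    make_pair, render


@pytest.fixture(scope="session")
def zero_noise_phantom():
    """Rendered noiseless tree with ground truth, shared across tests."""
    spec = PhantomSpec(seed=3, noise=NoiseParams(noise_std=0.0,
                                                 illumination_amplitude=0.0))
    tree = generate_tree(spec)
    image, truth = render(tree, spec)
    return spec, tree, image, truth


@pytest.fixture(scope="session")
def rendered_pair():
    """A mildly noisy rendered phantom pair with a known similarity warp."""
    import math

    from fundusreg.transforms import SimilarityTransform

    warp = SimilarityTransform(1.05, math.radians(12), (20, 30))
    spec = PhantomSpec(seed=5, warp=warp, overlap_target=75,
                       noise=NoiseParams(noise_std=0.02,
                                         illumination_amplitude=0.1))
    return make_pair(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
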