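import numpy as np
import pytest

from mandmorph import synthgen
from mandmorph.landmark_io import LandmarkConfiguration
from mandmorph.scheme import LandmarkScheme, mandible_scheme


@pytest.fixture(scope="session")
def scheme():
    return mandible_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return synthgen.packaged_template(scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scheme():
    """A 5-landmark 3D scheme: 1 midline + 2 pairs."""
    return LandmarkScheme(
        names=("apex", "a_l", "b_l", "a_r", "b_r"),
        midline=(0,),
        pairs=((1, 3), (2, 4)),
        dimension=3,
    )


def random_configs(scheme, n, noise=0.1, seed=0, template=None):
    """Noisy copies of a base configuration, as LandmarkConfiguration list."""
    rng = np.random.default_rng(seed)
    k, d = len(scheme), scheme.dimension
    base = template if template is not None else rng.standard_normal((k, d)) * 10
    return [
        LandmarkConfiguration(
            f"s{i}", base + rng.standard_normal((k, d)) * noise, scheme
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def tiny_dataset():
    """Scaled-down synthetic dataset shared by slower tests."""
    cfg = synthgen.GeneratorConfig(
        seed=11, use_packaged_design=False, n_populations=6, n_per_population=10
    )
    return synthgen.generate(cfg)
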