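import warnings

import numpy as np
import pytest

from jforce.pipeline import PipelineConfig
from jforce.scenes import SceneConfig, make_scene

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*samples outside.*")


@pytest.fixture(scope="session")
def pair_scene():
    """A noise-free two-cell scene with exact ground truth."""
    return make_scene(SceneConfig(n_cells=2, topology="pair", seed=42))


@pytest.fixture(scope="session")
def chain4_scene():
    return make_scene(SceneConfig(n_cells=4, topology="chain", seed=7))


@pytest.fixture(scope="session")
def tree4_scene():
    return make_scene(SceneConfig(n_cells=4, topology="tree", seed=3))


@pytest.fixture(scope="session")
def triangle_scene():
    return make_scene(SceneConfig(n_cells=3, topology="loop", seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pipeline_config_for(truth) -> PipelineConfig:
    scfg = truth.config
    return PipelineConfig(
        pixel_size=scfg.pixel_size,
        substrate_modulus=scfg.substrate_modulus,
        substrate_poisson=scfg.substrate_poisson,
        seed=scfg.seed,
    )
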