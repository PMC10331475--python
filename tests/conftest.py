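import numpy as np
import pytest

from veqi.pipeline import PipelineConfig, run_pipeline
from veqi.synthetic import HumanPatch, LandusePatch, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """16 x 16 pixels, 8 years: one positive human patch, urban threat block."""
    return SceneConfig(
        n_rows=16, n_cols=16, n_years=8, seed=11,
        human_params=(HumanPatch(4, 8, 8, 12, 0.008),),
        landuse_patches=(LandusePatch(12, 16, 10, 14, "urban"),
                         LandusePatch(0, 4, 10, 14, "grass")),
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default 40 x 40, 20-year scene (seed 0)."""
    workdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(workdir=str(workdir), seed=0)
    manifest = run_pipeline(config)
    return config, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
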