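import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import illumibench as ib

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

REDUCED = dict(rows=250, cols=375)  # reduced test dimensions of the 1000x1500 default
SEED = 42


@pytest.fixture(scope="session")
def scene_specs():
    """The four default scenes at reduced dimensions."""
    return ib.default_scene_specs(rows=REDUCED["rows"], cols=REDUCED["cols"], seed=SEED)


@pytest.fixture(scope="session")
def clean_scene(scene_specs):
    """Rendered scene 1 (the simplest scene) with its ground truth."""
    return ib.render_scene(scene_specs[0])


@pytest.fixture(scope="session")
def shading_model():
    return ib.ShadingModel.linear(13)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def tiny_benchmark(tmp_path_factory, scene_specs):
    """A written-to-disk 1-scene, 2x2-grid benchmark plus its manifest."""
    outdir = tmp_path_factory.mktemp("bench")
    grid = ib.DistortionGrid(B=2, N=2, R_count=1)
    model = ib.ShadingModel.linear(grid.B)
    manifest = ib.generate_benchmark(scene_specs[:1], grid, model, outdir, seed=SEED)
    return outdir, manifest
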