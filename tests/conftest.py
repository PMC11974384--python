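import numpy as np
import pytest

import vemseg as v
from vemseg.model import NetworkSpec
from vemseg.preprocess import PatchSpec, normalize, tile


@pytest.fixture(scope="session")
def tiny_spec() -> NetworkSpec:
    """Smallest network that still exercises pooling and skip connections."""
    return NetworkSpec(levels=(3, 4), input_patch=(2, 8, 8))


@pytest.fixture(scope="session")
def blob_scene() -> v.SyntheticDataset:
    return v.generate_scene(v.SceneConfig(seed=5))


@pytest.fixture(scope="session")
def tiny_task(tiny_spec):
    """A miniature segmentation task: 8 patches of (2,8,8) plus a test scene."""
    cfg_tr = v.SceneConfig(grid_shape=(4, 16, 16), seed=31)
    cfg_te = v.SceneConfig(grid_shape=(2, 16, 16), seed=32)
    ds_tr = v.generate_scene(cfg_tr)
    ds_te = v.generate_scene(cfg_te)
    spec = PatchSpec(patch_shape=tiny_spec.input_patch)
    img = normalize(ds_tr.image, tile_grid=(2, 2))
    patches = [p.data for p in tile(img, spec)]
    labels = [p.data for p in tile(ds_tr.labels["M"], spec)]
    test_img = normalize(ds_te.image, tile_grid=(2, 2))
    return patches, labels, test_img, ds_te.labels["M"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
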