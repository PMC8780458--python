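import numpy as np
import pytest

from imfcnet.cp_heads import build_ifc_net, build_mfc_net
from imfcnet.data import load_dataset
from imfcnet.synthetic import SyntheticConfig, generate_synthetic, small_config


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """40 synthetic radiographs (10 per class) at a small raster."""
    root = tmp_path_factory.mktemp("synth_small")
    generate_synthetic(small_config(per_class=10, image_size=128, seed=3), root)
    return root


@pytest.fixture(scope="session")
def synth_index(synth_dir):
    return load_dataset(synth_dir)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """160 synthetic radiographs (40 per class) for the scaled-down
    cross-validated pipeline run."""
    root = tmp_path_factory.mktemp("synth_pipeline")
    generate_synthetic(small_config(per_class=40, image_size=128, seed=11),
                       root)
    return root


@pytest.fixture(scope="session")
def ifc_default():
    """Default full-size IFC-Net (random init, standalone head)."""
    return build_ifc_net(seed=0)


@pytest.fixture(scope="session")
def mfc_default():
    return build_mfc_net(seed=0)


def build_tiny_ifc(seed=0, input_size=96, width=0.35, with_head=True):
    return build_ifc_net(width_mult=width, input_size=input_size, seed=seed,
                         with_head=with_head)


def build_tiny_mfc(seed=0, input_size=64, width=0.35, with_head=True):
    return build_mfc_net(width_mult=width, input_size=input_size, seed=seed,
                         with_head=with_head)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
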