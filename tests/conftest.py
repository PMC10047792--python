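import numpy as np
import pytest

from eitshape.mesh import DomainSpec, build_disk_mesh
from eitshape.phantoms import DatasetConfig, build_dataset


@pytest.fixture(scope="session")
def training_mesh():
    return build_disk_mesh(DomainSpec(), 0.08)


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_disk_mesh(DomainSpec(), 0.25)


@pytest.fixture(scope="session")
def tiny_datasets(training_mesh):
    """A small simulated train/val pair shared across training tests."""
    cfg = DatasetConfig(n_train_per_class=3, n_val=8, master_seed=1)
    train = build_dataset(cfg, training_mesh, "train")
    val = build_dataset(cfg, training_mesh, "val")
    return train, val


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
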