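import numpy as np
import pytest

from holoprot import (
    BasisSpec,
    NetworkConfig,
    encode,
    make_class_dataset,
    make_polyalanine,
    train,
)


@pytest.fixture(scope="session")
def basis_small() -> BasisSpec:
    return BasisSpec(l_max=4, n_max=6, r_max=10.0)


@pytest.fixture(scope="session")
def class_dataset_small():
    """3 geometric classes x 20 samples, modest jitter."""
    return make_class_dataset(n_classes=3, n_per_class=20, jitter=0.25, seed=11)


@pytest.fixture(scope="session")
def encoded_small(class_dataset_small, basis_small):
    return [(encode(nb, basis_small), lab) for nb, lab in class_dataset_small]


@pytest.fixture(scope="session")
def tiny_trained_model(encoded_small):
    """A small classifier trained briefly on the 3-class fixture."""
    cfg = NetworkConfig(n_layers=2, mode="simply", hidden_channels=6, l_max=3,
                        head_widths=(24,), seed=3)
    model, log = train(encoded_small, cfg, epochs=40, lr=2e-3, seed=3)
    return model, log


@pytest.fixture()
def helix():
    return make_polyalanine(14, phi=-57.0, psi=-47.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
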