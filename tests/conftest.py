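import numpy as np
import pytest

from leafseg.synthleaf import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """10-image synthetic dataset (8 train / 1 val / 1 test), shared read-only."""
    root = tmp_path_factory.mktemp("leafdata")
    manifest = generate_dataset(n=10, n_species=2, img_size=64, seed=42, out_dir=root)
    return root, manifest
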