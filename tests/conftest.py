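import numpy as np
import pytest

import polypscan as ps

# One seed for the whole suite's study conditions.
SEED = 7


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick fixture set for unit tests: 12 polyp / 24 nonpolyp windows."""
    return ps.make_dataset(12, 24, seed=SEED)


@pytest.fixture(scope="session")
def random_window(rng):
    return ps.Window(pixels=rng.integers(0, 256, (227, 227, 3), dtype=np.uint8), origin=(0, 0))


@pytest.fixture(scope="session")
def fusion_run():
    """The desk-scale evaluation: 300 windows (1:2 polyp:nonpolyp),
    stratified 70/30 split, CNN trained 3 epochs, three SVMs (CW-only,
    CNN-only, fused).  Shared across the end-to-end tests because it is the
    expensive part of the suite."""
    return ps.fusion_benchmark(n_polyp=100, n_nonpolyp=200, seed=SEED, cnn_epochs=3)


@pytest.fixture(scope="session")
def trained_detector(fusion_run):
    """Detector assembled from the fusion run's fitted components."""
    return ps.PolypDetector(
        cw_extractor=fusion_run["extractors"]["cw"],
        cnn_extractor=fusion_run["extractors"]["cnn"],
        classifier=fusion_run["models"]["fused"],
        positive_class=1,
    )
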