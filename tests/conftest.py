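import numpy as np
import pytest

from dropsort.classifier import TrainConfig, ViabilityCNN, build_cnn
from dropsort.imaging import ImagingParams, generate_dataset

# The standard synthetic benchmark: 400 dispensed single cells, half viable,
# default imaging.  Shared (read-only) across test modules.
BENCH_N, BENCH_CV, BENCH_SEED = 400, 0.5, 7


@pytest.fixture(scope="session")
def bench_dataset():
    manifest, crops = generate_dataset(BENCH_N, BENCH_CV, seed=BENCH_SEED)
    return manifest, crops


@pytest.fixture(scope="session")
def trained_model(bench_dataset):
    """CNN-4/32 trained 30 epochs on the benchmark (the learning-sanity setting)."""
    manifest, crops = bench_dataset
    model = ViabilityCNN(
        crops,
        manifest["label"].to_numpy(),
        spec=build_cnn(4, 32),
        split=manifest["split"].to_numpy(),
    )
    return model.fit(TrainConfig(epochs=30, seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 80-crop set on small frames for fast unit-level training."""
    params = ImagingParams(frame_size=(100, 100))
    manifest, crops = generate_dataset(80, 0.5, params=params, seed=21)
    return manifest, crops
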