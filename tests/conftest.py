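import numpy as np
import pytest

from ftirdx.io import SpectralDataset
from ftirdx.preprocess import preprocess_pipeline
from ftirdx.io import average_replicates
from ftirdx.simulate import GeneratorConfig, generate


def small_dataset(n_wn: int = 20, n_spec: int = 3, reps: int = 2,
                  seed: int = 0) -> SpectralDataset:
    """A tiny labelled dataset on a descending axis, for I/O round trips."""
    rng = np.random.default_rng(seed)
    wn = np.linspace(1800.0, 900.0, n_wn)
    labels = ["normal", "barretts", "oac", "lgd", "hgd", "inflammatory"]
    sids, repl, labs, rows = [], [], [], []
    for i in range(n_spec):
        for r in range(1, reps + 1):
            sids.append(f"P{i}")
            repl.append(r)
            labs.append(labels[i % len(labels)])
            rows.append(rng.random(n_wn))
    return SpectralDataset(wn, np.vstack(rows), np.array(sids, dtype=object),
                           np.array(repl), np.array(labs, dtype=object))


@pytest.fixture
def tiny_ds() -> SpectralDataset:
    return small_dataset()


@pytest.fixture(scope="session")
def default_raw():
    """The generator's default dataset (109 specimens x 10 replicates)."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def specimens_separable():
    """Preprocessed per-specimen data at strong separation, no overlap."""
    ds, truth = generate(GeneratorConfig(seed=5, separation=10.0, overlap=0.0))
    sp = average_replicates(preprocess_pipeline(ds))
    return sp, truth


@pytest.fixture(scope="session")
def specimens_default():
    """Preprocessed per-specimen data at the default operating point."""
    ds, truth = generate(GeneratorConfig(seed=11))
    sp = average_replicates(preprocess_pipeline(ds))
    return sp, truth
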