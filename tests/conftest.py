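import numpy as np
import pytest

from hsslda import synthetic
from hsslda.containers import CellMatrix, Embedding, LabelVector


@pytest.fixture(scope="session")
def blobs500():
    """Canonical discrete fixture: 500 cells, 3 classes, 2 informative + 4
    noise features, centroids 6 within-class SDs apart."""
    spec = synthetic.BlobSpec(
        k=3, p_informative=2, p_noise=4,
        class_sizes=[167, 167, 166], separation=6.0, seed=7,
    )
    return synthetic.make_blobs(spec)


@pytest.fixture(scope="session")
def cycle2000():
    """Canonical cyclic fixture: 2,000 cells, 5 phases, default noise."""
    spec = synthetic.CycleSpec(n=2000, seed=11)
    return synthetic.make_cycle(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def embedding_of(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or [f"c{i}" for i in range(len(coords))]
    return Embedding(coords, ids)


def labels_of(values, classes=None, cyclic=False):
    return LabelVector(np.asarray(values), classes or [], cyclic)


def matrix_of(values, features=None, ids=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{j + 1}" for j in range(values.shape[1])]
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return CellMatrix(values, features, ids)
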