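import numpy as np
import pytest

from timsrescore import (
    SyntheticDatasetSpec,
    SyntheticPredictor,
    generate_dataset,
)
from timsrescore.annotation import LAYOUT_SIZE, IntensityVector


def make_vector(values, valid=None):
    """Build an IntensityVector with the given leading values valid."""
    v = np.full(LAYOUT_SIZE, -1.0)
    m = np.zeros(LAYOUT_SIZE, dtype=bool)
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.arange(values.size)
    valid = np.asarray(valid)
    v[valid] = values
    m[valid] = True
    return IntensityVector(v, m)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small seeded benchmark shared by read-only tests."""
    return generate_dataset(SyntheticDatasetSpec(n_peptides=200, seed=3))


@pytest.fixture(scope="session")
def tiny_predictor(tiny_dataset):
    return SyntheticPredictor(tiny_dataset.model)


@pytest.fixture(scope="session")
def tiny_spectra_by_id(tiny_dataset):
    return {s.spectrum_id: s for s in tiny_dataset.spectra}
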