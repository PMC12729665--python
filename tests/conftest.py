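import numpy as np
import pytest

from myofat.features import CalibrationRecord
from myofat.io import RunConfig
from myofat.phantoms import AcousticModel, DatasetManifest, build_phantom_grid
from myofat.pipeline import extract_dataset


@pytest.fixture(scope="session")
def calib() -> CalibrationRecord:
    return CalibrationRecord.from_excitations()


@pytest.fixture(scope="session")
def grid_records(calib):
    """Full 25x15 criterion-record table with the default calibrated model."""
    manifest = DatasetManifest(build_phantom_grid(), repeats=15, seed=1)
    return extract_dataset(manifest, calib)


@pytest.fixture(scope="session")
def noisefree_records(calib):
    """Two noise-free repeats of every grid phantom."""
    manifest = DatasetManifest(build_phantom_grid(), repeats=2, seed=3,
                               model=AcousticModel().noiseless())
    return extract_dataset(manifest, calib)


@pytest.fixture(scope="session")
def split_pair(grid_records):
    """Train = repeats 4..15, test = repeats 1..3."""
    test = grid_records[grid_records["repeat"] <= 3]
    train = grid_records[grid_records["repeat"] > 3]
    return train, test
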