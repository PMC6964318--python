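import numpy as np
import pytest

from batmri.core import AcquisitionParams, RoiMask
from batmri.phantom import PhantomTruth, generate_phantom


@pytest.fixture(scope="session")
def small_truth():
    """Small deterministic phantom shared by read-only tests."""
    return generate_phantom(shape=(32, 32, 8), seed=7)


@pytest.fixture(scope="session")
def default_acq():
    return AcquisitionParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_uniform_truth(ff_value, t2s=15.0, shape=(16, 16, 4), voxel_volume=1.0,
                       fieldmap=0.0):
    """Truth volume with constant FF inside a box ROI (helper for formula tests)."""
    ff = np.full(shape, float(ff_value))
    roi = np.zeros(shape, dtype=bool)
    roi[2:-2, 2:-2, 1:-1] = True
    sat = np.zeros(shape, dtype=bool)
    return PhantomTruth(ff_true=ff, t2s_true=np.full(shape, t2s),
                        fieldmap_true=np.full(shape, float(fieldmap)),
                        roi=roi, sat_roi=sat, pd=np.ones(shape),
                        voxel_volume=voxel_volume)


def box_roi(shape, voxel_volume=1.0, label="supraclavicular"):
    values = np.zeros(shape)
    values[1:-1, 1:-1, 1:-1] = 1.0
    return RoiMask(values=values, voxel_volume=voxel_volume, label=label)
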