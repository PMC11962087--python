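import numpy as np
import pytest

from lpbarcode import (
    JointBarcodeDistribution,
    NoiseModel,
    SpectralDistribution,
    TaggingMixture,
)


@pytest.fixture
def uniform100():
    return SpectralDistribution.uniform(100.0, center=950.0)


@pytest.fixture
def joint_uniform100(uniform100):
    return JointBarcodeDistribution(base=uniform100)


@pytest.fixture
def joint_gauss100():
    return JointBarcodeDistribution(
        base=SpectralDistribution.gaussian(delta_big=100.0, center=950.0))


@pytest.fixture
def gaussian_noise01():
    return NoiseModel.gaussian(0.1)


@pytest.fixture
def fixed_m3():
    return TaggingMixture(mode="fixed", m=3)


def _pool_from_matrix(mat, prefix="cell"):
    """Build a BarcodePool from an (n, m) sorted-energy matrix."""
    from lpbarcode import BarcodePool

    mat = np.asarray(mat, dtype=float)
    return BarcodePool([f"{prefix}{i:06d}" for i in range(mat.shape[0])],
                       list(mat))


@pytest.fixture
def pool_from_matrix():
    return _pool_from_matrix
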