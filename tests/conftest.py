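import numpy as np
import pytest

from dcfmri.core import BoldScan


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_dc_scan():
    """Four voxel series with hand-computable pairwise correlations:
    r(1,2)=1, r(1,3)=-1, r(1,4)=0.8, r(2,4)=0.8, r(3,4)=-0.8."""
    data = np.zeros((4, 1, 1, 4))
    data[0, 0, 0] = [1, 2, 3, 4]
    data[1, 0, 0] = [2, 4, 6, 8]
    data[2, 0, 0] = [4, 3, 2, 1]
    data[3, 0, 0] = [1, 3, 2, 4]
    mask = np.ones((4, 1, 1), dtype=bool)
    return BoldScan(data=data, affine=np.eye(4), tr_s=2.0, subject_id="w"), mask


@pytest.fixture
def random_scan(rng):
    data = rng.standard_normal((6, 6, 1, 40))
    return BoldScan(data=data, affine=np.eye(4), tr_s=2.0, subject_id="r")
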