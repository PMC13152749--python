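import numpy as np
import pytest

from ctdem import BinaryMask, DemParams, ImageVolume, generate_dem, make_lesion
from ctdem.synthetic import benign_spec, metastatic_spec


@pytest.fixture(scope="session")
def benign_dem():
    """DEM + mask of one benign-like phantom (session-cached)."""
    vol, mask, _ = make_lesion(benign_spec(seed=11))
    return generate_dem(vol, mask, DemParams())


@pytest.fixture(scope="session")
def metastatic_dem():
    """DEM + mask of one metastatic-like phantom (session-cached)."""
    vol, mask, _ = make_lesion(metastatic_spec(seed=11))
    return generate_dem(vol, mask, DemParams())


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def ellipsoid_mask():
    z, y, x = np.ogrid[:20, :20, :20]
    data = ((x - 9.5) / 6) ** 2 + ((y - 9.5) / 7) ** 2 + ((z - 9.5) / 8) ** 2 <= 1
    return BinaryMask(data)
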