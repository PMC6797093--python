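import numpy as np
import pytest

import bananacount as bc


@pytest.fixture(scope="session")
def farm_scene():
    """A mid-size synthetic farm spanning several overlap tiles (seeded)."""
    spec = bc.FarmSpec(rows=9, cols=14, seed=7, missing_prob=0.1, sucker_prob=0.3)
    img, gt = bc.render_farm(spec)
    return spec, img, gt


@pytest.fixture()
def rgb_ramp():
    """A 3-band image whose bands each span the full [0, 255] range."""
    band = np.arange(256, dtype=np.uint8).reshape(16, 16)
    return bc.RasterImage(np.stack([band, band.T, band[::-1]], axis=-1))
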