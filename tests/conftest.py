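import numpy as np
import pytest

import pestspread as ps


@pytest.fixture(scope="session")
def default_landscape():
    """The baseline 5×5 farm (250 000 suitable pixels, 608 m side)."""
    return ps.build_landscape()


@pytest.fixture(scope="session")
def small_landscape():
    """A 2×2 farm of 20 m fields — cheap enough for brute-force checks."""
    lay = ps.LandscapeLayout(fields_per_side=2, field_size=20,
                             division_width=2, buffer_width=6, pixel_size=1)
    return ps.build_landscape(lay)


@pytest.fixture
def rng():
    return np.random.default_rng(20180321)


@pytest.fixture(scope="session")
def fast_params():
    """Quick-maturing population parameters for cheap spread tests."""
    return ps.PopulationParams(p_max=400, t_0=1, t_50=4, p_estab=0.05)
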