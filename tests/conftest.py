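import numpy as np
import pytest

from prioritygrid.grids import GridSpec
from prioritygrid.synthetic import make_world


@pytest.fixture
def fine_spec():
    return GridSpec(origin_lon=0.0, origin_lat=4.8, cell_size=0.1,
                    n_rows=48, n_cols=48)


@pytest.fixture
def small_spec():
    return GridSpec(origin_lon=0.0, origin_lat=2.0, cell_size=0.1,
                    n_rows=20, n_cols=20)


@pytest.fixture
def world(fine_spec):
    return make_world(seed=11, fine_spec=fine_spec, nesting_factor=4,
                      n_species=4, n_predictors=4, records_per_species=20,
                      reserve_fraction=0.1)
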