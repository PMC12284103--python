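import numpy as np
import pytest

from microcort.synthetic_cortex import gen_parcel_sphere
from microcort.synthetic_signals import gen_scheme
from microcort.tissue_models import build_noddi_dictionary


@pytest.fixture(scope="session")
def small_geom():
    """40 parcels, 320 vertices — fast geometry for unit tests."""
    return gen_parcel_sphere(20, 8, seed=1)


@pytest.fixture(scope="session")
def std_geom():
    """Full-size 360-parcel geometry for spin/statistics tests."""
    return gen_parcel_sphere(180, 30, seed=1)


@pytest.fixture(scope="session")
def hcp_scheme():
    return gen_scheme("hcp_like")


@pytest.fixture(scope="session")
def mgh_scheme():
    return gen_scheme("mgh")


@pytest.fixture(scope="session")
def noddi_dict(hcp_scheme):
    return build_noddi_dictionary(hcp_scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
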