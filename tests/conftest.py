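import numpy as np
import pytest

from wbcm.model import GridGeometry, LulccRaster, default_legend, default_mapping
from wbcm.params import CarbonParamTable
from wbcm.soil import STANDARD_LAYERS, SoilLayer, SoilProfile


@pytest.fixture(scope="session")
def param_table():
    return CarbonParamTable.default()


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def legend():
    return default_legend()


def make_profile(site_id="p0", lulcc_class="FOR", bd=1.3, oc=8.0, layers=STANDARD_LAYERS):
    """Uniform-property profile over the standard 7 layers."""
    bd = np.broadcast_to(np.asarray(bd, float), (len(layers),))
    oc = np.broadcast_to(np.asarray(oc, float), (len(layers),))
    return SoilProfile(
        site_id=site_id,
        lulcc_class=lulcc_class,
        layers=tuple(
            SoilLayer(a, b, float(bd[i]), float(oc[i]))
            for i, (a, b) in enumerate(layers)
        ),
    )


def uniform_raster(code, shape=(10, 10), year=1990, pixel_size=30.0):
    geom = GridGeometry.square(shape, pixel_size)
    return LulccRaster(
        year=year, grid=np.full(shape, code, dtype=np.uint8), geometry=geom
    )


@pytest.fixture
def make_profile_fn():
    return make_profile


@pytest.fixture
def uniform_raster_fn():
    return uniform_raster
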