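import numpy as np
import pytest

import sprkit as sk
from sprkit.hlut import reference_attenuation_fit


@pytest.fixture(scope="session")
def lib():
    return sk.default_library()


@pytest.fixture(scope="session")
def raw_lib():
    """Library with the unanchored (gas-phase) elemental I-values."""
    return sk.default_library(anchor_water_ivalue=None)


@pytest.fixture(scope="session")
def tissues(lib):
    return lib.by_category("reference_human_tissue")


@pytest.fixture(scope="session")
def surrogates(lib):
    return lib.by_category("tissue_surrogate")


@pytest.fixture(scope="session")
def atten_fit(lib):
    return reference_attenuation_fit(lib.elements)


@pytest.fixture(scope="session")
def ivalue_mapping(lib, tissues):
    return sk.fit_ivalue_mapping(tissues, lib.elements)


@pytest.fixture(scope="session")
def default_hlut(lib, tissues, atten_fit):
    return sk.build_hlut(atten_fit, tissues + [lib["water"]], lib.elements)


@pytest.fixture(scope="session")
def sc_coarse(lib):
    """SC phantom rasterized at 2 mm (fast enough for ensemble tests)."""
    geom = sk.builtin_geometries()["SC"]
    return sk.rasterize(geom, lib, spacing=(2.0, 2.0, 2.0))


def uniform_spr_volume(value=1.0, shape=(101, 21, 21), spacing=(1.0, 1.0, 1.0)):
    return sk.ImageVolume(np.full(shape, float(value)), spacing, (0.0, 0.0, 0.0), "SPR")
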