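import numpy as np
import pytest

from capsfem.config import ScenarioConfig, run_pipeline
from capsfem.geometry import GeometryParams, generate_capsule, make_fixture
from capsfem.materials import RegionMaterial, YeohMaterial, region_materials

TABLE1 = {
    "antero_superior": (20.5, -26.5, 185.3, 2.8),
    "posterior": (13.2, -19.6, 125.9, 1.5),
    "ab_ighl": (11.9, -11.1, 95.8, 2.8),
    "pb_ighl": (29.1, -18.4, 206.5, 1.3),
    "axillary_pouch": (0.22, -17.4, 111.9, 4.3),
}


@pytest.fixture(scope="session")
def default_materials():
    return region_materials()


@pytest.fixture(scope="session")
def default_capsule(default_materials):
    return generate_capsule(GeometryParams(), default_materials)


@pytest.fixture(scope="session")
def small_capsule(default_materials):
    """Coarse capsule for fast solver tests."""
    return generate_capsule(
        GeometryParams(n_circ=16, n_axial=4), default_materials
    )


@pytest.fixture()
def flat_patch():
    return make_fixture("flat_patch", n=4, thickness=1.0)


@pytest.fixture()
def neo_hookean_patch_material():
    return {"patch": RegionMaterial(YeohMaterial(1.0), 1.0)}


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One full healthy + three-lesion study at the default configuration.

    Session-scoped: the comparison-study assertions (strain ordering,
    lesion similarity, compliance ordering) all read from this single run.
    """
    return run_pipeline(ScenarioConfig())
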