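import numpy as np
import pytest

from brachydeck import phantoms, sources, tg43
from brachydeck.materials import BinningScheme, HUCalibration, TissueTable


@pytest.fixture(scope="session")
def small_spec():
    """Coarse water sphere: 30 mm radius, 32^3-ish grid, fast to build."""
    return phantoms.PhantomSpec(radius=30.0, fov=80.0, matrix=32,
                                slice_thickness=2.5, n_slices=32)


@pytest.fixture(scope="session")
def small_ct(small_spec):
    return phantoms.make_water_sphere_ct(small_spec)


@pytest.fixture(scope="session")
def single_plan(small_ct):
    return phantoms.make_single_dwell_plan(center=small_ct.center(),
                                           time=300.0)


@pytest.fixture(scope="session")
def multicath_plan():
    return phantoms.make_multicatheter_plan(n_catheters=6,
                                            dwells_per_catheter=10,
                                            spacing=5.0, seed=42)


@pytest.fixture(scope="session")
def source_data():
    return tg43.TG43SourceData.synthetic(Sk=40000.0)


@pytest.fixture(scope="session")
def calibration():
    return HUCalibration.default()


@pytest.fixture(scope="session")
def scheme():
    return BinningScheme.default()


@pytest.fixture(scope="session")
def tissue_table():
    return TissueTable.default()


@pytest.fixture(scope="session")
def fine_dose(source_data):
    """1 mm isotropic dose cube around a single centered dwell.

    The dwell sits exactly on a voxel center so transverse-axis sample
    points fall on grid nodes; shared by the g/F recovery tests.
    """
    plan = phantoms.make_single_dwell_plan(center=(0.0, 0.0, 0.0),
                                           time=300.0)
    n = 121   # 12 cm cube: covers r <= 5 cm everywhere it is sampled
    origin = -np.ones(3) * (n - 1) / 2.0
    dose = tg43.render_rtdose(plan, source_data, origin, np.ones(3),
                              (n, n, n))
    pose = sources.dwell_transform(plan.dwells[0], plan.catheters[0])
    return dose, pose
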