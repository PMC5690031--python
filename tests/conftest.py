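import numpy as np
import pytest

from kvdose import materials as M
from kvdose import phantoms_io as ph
from kvdose import source_characterization as sc
from kvdose import source_model as sm


@pytest.fixture(scope="session")
def xs():
    return M.CrossSectionTable.default()


@pytest.fixture(scope="session")
def water_cube():
    """32^3 homogeneous water cube with 1 cm voxels, centered on isocenter."""
    hu = np.zeros((32, 32, 32), dtype=np.int16)
    return ph.VoxelPhantom(hu, (10.0, 10.0, 10.0), (-15.5, -15.5, -15.5))


@pytest.fixture(scope="session")
def water_scheme():
    return M.get_scheme("water")


@pytest.fixture(scope="session")
def vacuum_scheme():
    return M.SegmentationScheme("all_vacuum", ((-1024, 10000, M.VACUUM),))


@pytest.fixture(scope="session")
def mist_scheme():
    """Water composition at near-zero density: kerma of water, no attenuation."""
    mist = M.Material("water_mist", dict(M.WATER.composition), 1e-12)
    return M.SegmentationScheme("all_mist", ((-1024, 10000, mist),))


def make_mono_source(energy=60.0, blades=(5.0, 5.0, 5.0, 5.0), arc_deg=1.0,
                     arc_start=0.0, mas=100.0, output=0.01, sad=100.0):
    spec = sm.EnergySpectrum(np.array([energy]), np.array([1.0]))
    return sm.VirtualPointSource(
        kvp=150.0, spectrum_map=sm.SpectrumMap.uniform(spec, 50.0),
        fluence=sm.PlanarFluence.flat(), blades=blades, arc_start_deg=arc_start,
        arc_deg=arc_deg, sad=sad, mas=mas, output_cgy_per_mas=output)


@pytest.fixture(scope="session")
def mono60_source():
    return make_mono_source(60.0)


@pytest.fixture(scope="session")
def coarse_cylinder():
    """The 15.2 cm x 22 cm acrylic cylinder on a coarser grid (for speed)."""
    return ph.make_cylinder_phantom(dims=(256, 256, 46),
                                    spacing_mm=(1.62, 1.62, 6.0))


@pytest.fixture(scope="session")
def acrylic_scheme():
    return M.get_scheme("acrylic")


@pytest.fixture(scope="session")
def pelvis_source():
    return sc.characterized_protocol_source("pelvis")
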