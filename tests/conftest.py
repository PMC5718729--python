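import numpy as np
import pytest

import ctdose
from ctdose import dose_engine as de


@pytest.fixture(scope="session")
def default_model():
    """Synthetic head-bowtie 120 kVp / 10 mm commissioning set."""
    return ctdose.generate_synthetic_beam_model(seed=0)


@pytest.fixture(scope="session")
def water_cylinder():
    """160 mm water cylinder, coarse resolution, as a density grid."""
    grid = ctdose.make_cylinder(160.0, 160.0, 0.0, spacing=(4.0, 4.0, 8.0))
    return ctdose.hu_to_density(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def flat_model():
    """Degenerate model: unit TMR and unit profiles over a wide support."""
    from ctdose.beam_model import BeamModel, CTDITable, CrossProfile, TMRCurve

    tmr = TMRCurve(depths=np.array([0.0, 500.0, 1000.0]),
                   values=np.array([1.0, 1.0, 1.0]))
    px = CrossProfile(axis="transaxial_x",
                      offsets=np.array([-400.0, 0.0, 400.0]),
                      values=np.array([1.0, 1.0, 1.0]))
    pz = CrossProfile(axis="longitudinal_z",
                      offsets=np.array([-400.0, 0.0, 400.0]),
                      values=np.array([1.0, 1.0, 1.0]))
    ctdi = CTDITable(diameters=np.array([100.0, 320.0]),
                     center_dose=np.array([30.0, 30.0]))
    return BeamModel(tmr=tmr, profile_x=px, profile_z=pz, ctdi=ctdi)


def uniform_box_density(n=(40, 21, 21), spacing=(2.0, 2.0, 2.0), value=1.0):
    """Axis-aligned homogeneous box; exact path lengths for ray tests."""
    vals = np.full(n, value)
    origin = tuple(-(ni - 1) / 2.0 * si for ni, si in zip(n, spacing))
    return ctdose.VoxelGrid(values=vals, spacing=spacing, origin=origin,
                            value_kind="density")
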