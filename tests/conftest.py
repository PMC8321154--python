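"""Shared fixtures: small, fast synthetic scenes.

Everything is generated at run time; the bead light-field is session-scoped
because the 81-view acquisition is the slowest shared ingredient.
"""

import numpy as np
import pytest

from xlfemu import presets
from xlfemu.geometry import OpticalAxisFrame
from xlfemu.phantom import Phantom, Primitive
from xlfemu.projector import AcquisitionSettings, acquire_lightfield

Z0 = presets.Z0

BEAD_Z = Z0 + 10.0
BEAD_XY = (1.0, -0.5)


@pytest.fixture(scope="session")
def small_geometry():
    """Reference frame, 9×9 views, reduced 64×64 detector."""
    return presets.reference_geometry(detector_pixels=(64, 64))


@pytest.fixture(scope="session")
def bead_phantom():
    """A single dense bead 10 mm behind the focal plane."""
    bead = Primitive("sphere", (*BEAD_XY, BEAD_Z), 0.4, 0.5)
    return Phantom(
        shape=(40, 40, 160),
        voxel_size=0.1,
        origin=(-1.0, -2.5, BEAD_Z - 8.0),
        primitives=(bead,),
    )


@pytest.fixture(scope="session")
def bead_lightfield(small_geometry, bead_phantom):
    """Noiseless 81-view acquisition of the bead."""
    return acquire_lightfield(
        bead_phantom, small_geometry, AcquisitionSettings(noise=False)
    )


@pytest.fixture
def tiny_frame():
    return OpticalAxisFrame(z0=100.0, zsd=150.0)
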