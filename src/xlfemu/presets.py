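"""Reference configuration: the published emulation experiment.

The reference setup emulates a conceptual decoding-lens X-ray plenoptic
camera on a flexible cone-beam scanner: 128×128-pixel PHIs at 150 μm pitch,
acquired on a 9×9 source grid with 2 mm spacing, with z0 = 890.725 mm and
zsd = 1012.95 mm.  The emulated camera uses a 1000 μm Fresnel-zone-plate main
lens 49.48 mm from the sample, a 128×128 micro-lens array (32 μm lenses,
36 μm pitch) at z1 = 243.71 mm, and a 4 μm-pixel sensor at z2 = 8.78 mm.
"""

from __future__ import annotations

from .geometry import (
    EmulationGeometry,
    LensDesign,
    OpticalAxisFrame,
    grid_emulation_geometry,
)

#: mm, source-to-focal-plane distance of the reference scan
Z0 = 890.725
#: mm, source-to-detector distance of the reference scan
ZSD = 1012.95
#: mm, spacing of the 9×9 source grid
SOURCE_SPACING = 2.0
#: detector pixels per PHI
DETECTOR_PIXELS = (128, 128)
#: μm, scanner detector pixel pitch
DETECTOR_PITCH = 150.0
#: views per axis
N_VIEWS = 9


def reference_frame() -> OpticalAxisFrame:
    return OpticalAxisFrame(z0=Z0, zsd=ZSD)


def reference_lens_design() -> LensDesign:
    """The emulated camera.  f1 follows from the thin-lens relation
    1/f1 = 1/z0_cam + 1/z1; the sensor sits at the MLA focal distance
    (unfocused configuration, z2 = f2).  With a 36 μm micro-lens pitch and
    4 μm sensor pixels there are 9×9 usable views."""
    z0_cam, z1, z2 = 49.48, 243.71, 8.78
    f1 = 1.0 / (1.0 / z0_cam + 1.0 / z1)
    return LensDesign(
        f1=f1,
        f2=z2,
        z0_cam=z0_cam,
        z1=z1,
        z2=z2,
        ml_diameter=1000.0,
        mla_lens_diameter=32.0,
        mla_pitch=36.0,
        sensor_pixel=4.0,
        n_views_u=N_VIEWS,
        n_views_v=N_VIEWS,
    )


def reference_geometry(
    detector_pixels: tuple[int, int] = DETECTOR_PIXELS,
    n_views: int = N_VIEWS,
    spacing: float = SOURCE_SPACING,
) -> EmulationGeometry:
    """The 9×9 / 2 mm reference scan geometry (sizes overridable for
    reduced-scale runs)."""
    return grid_emulation_geometry(
        reference_frame(),
        n_views_u=n_views,
        n_views_v=n_views,
        spacing_u=spacing,
        detector_pixels=detector_pixels,
        detector_pitch=DETECTOR_PITCH,
    )
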