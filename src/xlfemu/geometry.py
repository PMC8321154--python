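"""Apparatus designs and their emulation scan geometries.

An X-ray plenoptic camera records a grid of pin-hole images (PHIs), one per
viewing direction.  A flexible cone-beam scanner can emulate any such camera
by moving the point source to a set of transverse positions ``S(u, v)`` in the
source plane and the detector center to matching positions ``D(u, v)``, chosen
so that every source→detector-center line crosses the optical axis at the
focal plane ``z = z0``.  This module converts the three known apparatus
families — a large diffracting crystal, tapered poly-capillary optics, and a
(conceptual) decoding-lens camera — into such ``(S, D)`` position sets, and
computes the derived quantities (angular range, spatial/angular resolution,
magnification, beamlet waist, depth-of-field style bounds) needed to judge a
design's feasibility.

Conventions
-----------
* All stored lengths are mm; μm is accepted at the interface for lens, pixel
  and capillary dimensions and converted on input.
* The optical axis is ``z``; the source plane sits at ``z = 0``, the focal
  plane at ``z = z0`` and the detector plane at ``z = zsd``.
* View grids are odd×odd so a central view ``(pu, pv) = (0, 0)`` exists; views
  are ordered row-major over ``(pv, pu)`` with ``pv`` outer, most negative
  first.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "OpticalAxisFrame",
    "ViewIndex",
    "CrystalDesign",
    "PolycapDesign",
    "LensDesign",
    "EmulationGeometry",
    "emulate_crystal",
    "emulate_polycap",
    "emulate_lens",
    "grid_emulation_geometry",
    "camera_resolutions",
    "angular_range",
    "emulation_pixel_size",
    "spatial_magnification",
    "to_camera_scale",
    "critical_angle",
    "beamlet_waist",
    "separation_ok",
    "parallax_depth_bound",
    "load_design",
    "save_design",
]

#: relative (zsd - z0) / z0 above which the parallel-beam (crystal) emulation
#: suffers noticeable cone-beam size/depth distortion.
CONE_DISTORTION_RATIO = 0.2


class GeometryError(ValueError):
    """Invalid or degenerate apparatus/emulation geometry."""


@dataclass(frozen=True)
class OpticalAxisFrame:
    """Axial layout of the emulation scanner.

    Parameters
    ----------
    z0:
        Source-plane-to-focal-plane distance (mm).
    zsd:
        Source-plane-to-detector-plane distance (mm).
    """

    z0: float
    zsd: float

    def __post_init__(self) -> None:
        if not (0.0 < self.z0 < self.zsd):
            raise GeometryError(
                f"require 0 < z0 < zsd, got z0={self.z0}, zsd={self.zsd}"
            )

    @property
    def cone_magnification(self) -> float:
        """Cone-beam magnification zsd / z0 of the focal plane."""
        return self.zsd / self.z0

    @property
    def focus_detector_distance(self) -> float:
        return self.zsd - self.z0


class ViewIndex(NamedTuple):
    """Signed grid index of one view; ``(0, 0)`` is the central view."""

    pu: int
    pv: int


@dataclass(frozen=True)
class View:
    """One emulated view: grid index, source and detector-center positions."""

    index: ViewIndex
    source: tuple[float, float]    # (u, v) mm in the source plane
    detector: tuple[float, float]  # (x, y) mm in the detector plane


@dataclass(frozen=True)
class CrystalDesign:
    """Diffracting-crystal apparatus: a parallel beam produces one transmitted
    and several Bragg-reflected beams; each forms a PHI centered at ``P(u,v)``
    on the detector.  The ``P`` positions are an input (they derive from the
    crystal's reciprocal lattice, which is outside this package's scope)."""

    phi_centers: tuple[tuple[float, float], ...]  # mm on the detector plane
    frame: OpticalAxisFrame

    def __post_init__(self) -> None:
        if len(self.phi_centers) == 0:
            raise GeometryError("crystal design needs at least one PHI center")
        has_central = any(
            abs(p[0]) < 1e-12 and abs(p[1]) < 1e-12 for p in self.phi_centers
        )
        if not has_central:
            raise GeometryError("crystal PHI centers must include the "
                                "transmitted beam at (0, 0)")


@dataclass(frozen=True)
class PolycapDesign:
    """Tapered poly-capillary apparatus: a pin-hole mask with hole pitch
    (δu, δv) is demagnified by the taper factor t = a_out / a_in."""

    hole_pitch_u: float  # mm (mask pitch δu)
    hole_pitch_v: float  # mm (mask pitch δv)
    n_views_u: int
    n_views_v: int
    a_in: float          # μm, neighbouring-capillary entrance distance
    a_out: float         # μm, neighbouring-capillary exit distance
    energy: float        # keV
    frame: OpticalAxisFrame

    def __post_init__(self) -> None:
        if self.a_in <= 0 or self.a_out <= 0:
            raise GeometryError("capillary distances must be positive")
        if self.energy <= 0:
            raise GeometryError("energy must be positive")
        _require_odd(self.n_views_u, self.n_views_v)

    @property
    def taper_factor(self) -> float:
        """Demagnification t = a_out / a_in of the pin-hole mask."""
        return self.a_out / self.a_in


@dataclass(frozen=True)
class LensDesign:
    """Decoding-lens (camera-style) apparatus: main lens (ML), micro-lens
    array (MLA) and sensor, in the unfocused plenoptic configuration
    (sensor at the MLA focal distance, z2 = f2)."""

    f1: float                # mm, ML focal distance
    f2: float                # mm, MLA focal distance
    z0_cam: float            # mm, sample-to-ML distance
    z1: float                # mm, ML-to-MLA distance
    z2: float                # mm, MLA-to-sensor distance
    ml_diameter: float       # μm
    mla_lens_diameter: float # μm
    mla_pitch: float         # μm
    sensor_pixel: float      # μm
    n_views_u: int
    n_views_v: int

    def __post_init__(self) -> None:
        if min(self.z0_cam, self.z1, self.z2) <= 0:
            raise GeometryError("camera distances must be positive")
        if not math.isclose(self.z2, self.f2, rel_tol=1e-6):
            raise GeometryError(
                "unfocused plenoptic configuration requires z2 = f2 "
                f"(got z2={self.z2}, f2={self.f2})"
            )
        _require_odd(self.n_views_u, self.n_views_v)


def _require_odd(*ns: int) -> None:
    for n in ns:
        if n < 1 or n % 2 == 0:
            raise GeometryError(
                f"view grids must be odd×odd so a central view exists, got {n}"
            )


@dataclass(frozen=True)
class EmulationGeometry:
    """Derived scan geometry: paired source / detector-center positions.

    ``detector_pitch`` and ``effective_pixel`` are in μm; positions in mm.
    """

    frame: OpticalAxisFrame
    views: tuple[View, ...]
    detector_pixels: tuple[int, int]  # (nx, ny)
    detector_pitch: float             # μm

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def effective_pixel(self) -> float:
        """Emulated pixel size (μm) at the focal plane: pitch / (zsd/z0)."""
        return emulation_pixel_size(self.detector_pitch, self.frame)

    @property
    def source_positions(self) -> np.ndarray:
        return np.array([v.source for v in self.views], dtype=float)

    @property
    def detector_positions(self) -> np.ndarray:
        return np.array([v.detector for v in self.views], dtype=float)

    @property
    def u_max(self) -> float:
        """Largest transverse source coordinate magnitude (mm)."""
        s = self.source_positions
        return float(np.max(np.abs(s))) if len(s) else 0.0

    @property
    def central_index(self) -> int:
        for i, v in enumerate(self.views):
            if v.index == (0, 0):
                return i
        raise GeometryError("geometry has no central (0, 0) view")

    @property
    def grid_shape(self) -> tuple[int, int] | None:
        """(Nv, Nu) when the views form a full odd grid, else None."""
        pu = sorted({v.index.pu for v in self.views})
        pv = sorted({v.index.pv for v in self.views})
        nu, nv = len(pu), len(pv)
        if nu * nv != self.n_views or nu % 2 == 0 or nv % 2 == 0:
            return None
        return (nv, nu)

    def angular_range(self) -> float:
        """Angular range (degrees) spanned by the view set."""
        return angular_range(self.u_max, self.frame.z0)

    def collinearity_residuals(self) -> np.ndarray:
        """Transverse offset (mm) of every S→D line from the axis at z0.

        Zero (to numerical precision) is the defining invariant of a valid
        plenoptic emulation: all view lines cross at the focal point.
        """
        s = self.source_positions
        d = self.detector_positions
        frac = self.frame.z0 / self.frame.zsd
        at_focus = s + (d - s) * frac
        return np.linalg.norm(at_focus, axis=1)

    def to_dict(self) -> dict:
        """JSON-serializable description (inverse of :meth:`from_dict`)."""
        return {
            "frame": {"z0": self.frame.z0, "zsd": self.frame.zsd},
            "views": [
                {"pu": v.index.pu, "pv": v.index.pv,
                 "source": list(v.source), "detector": list(v.detector)}
                for v in self.views
            ],
            "detector_pixels": list(self.detector_pixels),
            "detector_pitch": self.detector_pitch,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EmulationGeometry":
        views = tuple(
            View(
                index=ViewIndex(int(v["pu"]), int(v["pv"])),
                source=(float(v["source"][0]), float(v["source"][1])),
                detector=(float(v["detector"][0]), float(v["detector"][1])),
            )
            for v in payload["views"]
        )
        return cls(
            frame=OpticalAxisFrame(**payload["frame"]),
            views=views,
            detector_pixels=tuple(payload["detector_pixels"]),
            detector_pitch=float(payload["detector_pitch"]),
        )

    def scan_plan(self) -> pd.DataFrame:
        """Scan-plan table (one row per view) suitable for driving a scanner."""
        rows = [
            {
                "pu": v.index.pu,
                "pv": v.index.pv,
                "S_u_mm": v.source[0],
                "S_v_mm": v.source[1],
                "D_x_mm": v.detector[0],
                "D_y_mm": v.detector[1],
            }
            for v in self.views
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.scan_plan().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design → emulation geometry mappings
# ---------------------------------------------------------------------------

def emulate_crystal(
    design: CrystalDesign,
    detector_pixels: tuple[int, int] = (128, 128),
    detector_pitch: float = 150.0,
) -> EmulationGeometry:
    """Map a diffracting-crystal design to emulation positions.

    The crystal plane is the focal plane; each transmitted/diffracted beam
    center P becomes a detector position D = P, with the matching source at
    S = −z0/(zsd − z0)·P so the S→D line crosses the axis at z0.

    The crystal apparatus uses a parallel beam while the emulation uses a cone
    beam; the resulting size/depth distortion is tolerable only while
    (zsd − z0) ≪ z0, so a warning is emitted past that regime.
    """
    z0, zsd = design.frame.z0, design.frame.zsd
    if math.isclose(zsd, z0):
        raise GeometryError("zsd = z0 is degenerate for the crystal mapping")
    ratio = (zsd - z0) / z0
    if ratio > CONE_DISTORTION_RATIO:
        warnings.warn(
            f"(zsd - z0)/z0 = {ratio:.3f} > {CONE_DISTORTION_RATIO}: the "
            "cone-beam emulation of the parallel-beam crystal design will "
            "show size/depth distortion (no correction is applied)",
            stacklevel=2,
        )
    scale = -z0 / (zsd - z0)
    views = []
    # no natural grid for Bragg spots: preserve input order, central beam first
    centers = sorted(
        design.phi_centers, key=lambda p: (p[0] ** 2 + p[1] ** 2)
    )
    for k, p in enumerate(centers):
        views.append(
            View(
                index=ViewIndex(k, 0) if any(abs(c) > 1e-12 for c in p)
                else ViewIndex(0, 0),
                source=(scale * p[0], scale * p[1]),
                detector=(p[0], p[1]),
            )
        )
    return EmulationGeometry(
        frame=design.frame,
        views=tuple(views),
        detector_pixels=detector_pixels,
        detector_pitch=detector_pitch,
    )


def _grid_indices(nu: int, nv: int):
    hv, hu = nv // 2, nu // 2
    for pv in range(-hv, hv + 1):
        for pu in range(-hu, hu + 1):
            yield ViewIndex(pu, pv)


def grid_emulation_geometry(
    frame: OpticalAxisFrame,
    n_views_u: int,
    n_views_v: int,
    spacing_u: float,
    spacing_v: float | None = None,
    detector_pixels: tuple[int, int] = (128, 128),
    detector_pitch: float = 150.0,
) -> EmulationGeometry:
    """Regular-grid emulation geometry: S on a (pu, pv) grid with the given
    spacing (mm), D = −(zsd − z0)/z0 · S on the opposite side of the axis."""
    _require_odd(n_views_u, n_views_v)
    if spacing_v is None:
        spacing_v = spacing_u
    z0, zsd = frame.z0, frame.zsd
    dscale = -(zsd - z0) / z0
    views = []
    for idx in _grid_indices(n_views_u, n_views_v):
        su, sv = idx.pu * spacing_u, idx.pv * spacing_v
        views.append(
            View(index=idx, source=(su, sv), detector=(dscale * su, dscale * sv))
        )
    return EmulationGeometry(
        frame=frame,
        views=tuple(views),
        detector_pixels=detector_pixels,
        detector_pitch=detector_pitch,
    )


def emulate_polycap(
    design: PolycapDesign,
    detector_pixels: tuple[int, int] = (128, 128),
    detector_pitch: float = 150.0,
) -> EmulationGeometry:
    """Map a poly-capillary design to emulation positions.

    The pin-hole mask hole at H(u,v) = (pu·δu, pv·δv), demagnified by the
    taper factor t, yields a beamlet source at S = t·H and a PHI center at
    D = −(zsd − z0)/z0 · t·H.
    """
    if design.frame.z0 <= 0:
        raise GeometryError("z0 must be positive")
    t = design.taper_factor
    return grid_emulation_geometry(
        design.frame,
        design.n_views_u,
        design.n_views_v,
        spacing_u=t * design.hole_pitch_u,
        spacing_v=t * design.hole_pitch_v,
        detector_pixels=detector_pixels,
        detector_pitch=detector_pitch,
    )


def emulate_lens(
    design: LensDesign,
    frame: OpticalAxisFrame,
    spacing: float | None = None,
    detector_pixels: tuple[int, int] = (128, 128),
    detector_pitch: float = 150.0,
) -> EmulationGeometry:
    """Map a decoding-lens camera to emulation positions.

    Line integrals through the sample are direction-independent, so the PHI
    positions on the camera's main lens become X-ray source positions of the
    emulation, S(u,v) = (pu·δu', pv·δv'), with the detector at
    D = −(zsd − z0)/z0 · S.  The grid ``spacing`` δu' (mm) is a free emulation
    parameter; when omitted it is scaled from the camera's angular pitch by
    z0 / z0_cam so the emulation reproduces the camera's angular range.
    """
    if spacing is None:
        _, _, du, _ = camera_resolutions(design)
        spacing = (frame.z0 / design.z0_cam) * du * 1e-3  # μm → mm
    return grid_emulation_geometry(
        frame,
        design.n_views_u,
        design.n_views_v,
        spacing_u=spacing,
        detector_pixels=detector_pixels,
        detector_pitch=detector_pitch,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def camera_resolutions(design: LensDesign) -> tuple[float, float, float, float]:
    """(δs, δt, δu, δv) in μm of the camera itself.

    Spatial resolution δs, δt is the micro-lens pitch divided by the
    main-lens magnification |M| = z1 / z0; angular resolution δu, δv is the
    sensor pixel size divided by the micro-lens magnification |m| = z2 / z1.
    """
    big_m = design.z1 / design.z0_cam
    small_m = design.z2 / design.z1
    ds = design.mla_pitch / big_m
    du = design.sensor_pixel / small_m
    return (ds, ds, du, du)


def angular_range(u_max: float, z0: float) -> float:
    """Angular range (degrees): arctan of twice the maximum transverse source
    coordinate ``u_max`` (mm) divided by the focal distance ``z0`` (mm)."""
    if z0 <= 0:
        raise GeometryError("z0 must be positive")
    if u_max < 0:
        raise GeometryError("u_max must be non-negative")
    return math.degrees(math.atan(2.0 * u_max / z0))


def emulation_pixel_size(detector_pitch: float, frame: OpticalAxisFrame) -> float:
    """Effective pixel size (μm) at the focal plane: the detector pitch
    divided by the cone-beam magnification zsd / z0."""
    return detector_pitch * frame.z0 / frame.zsd


def spatial_magnification(emulation_pixel: float, camera_ds: float) -> float:
    """Spatial scale factor of the emulation relative to the camera (the
    emulation images a magnified version of the camera's object space)."""
    if emulation_pixel <= 0 or camera_ds <= 0:
        raise GeometryError("pixel sizes must be positive")
    return emulation_pixel / camera_ds


def to_camera_scale(length_mm: float, magnification: float) -> float:
    """Convert an emulation-scale length (mm) to the reference camera scale
    (μm), dividing by the nearest-integer spatial magnification."""
    return length_mm * 1e3 / round(magnification)


def critical_angle(energy: float) -> float:
    """Total-external-reflection critical angle (mrad) of borosilicate glass
    at the given X-ray energy (keV): φ ≈ 30 / E."""
    if energy <= 0:
        raise GeometryError("energy must be positive")
    return 30.0 / energy


def beamlet_waist(z0: float, energy: float) -> float:
    """Beamlet waist w = 2·z0·φ (μm) at the focal plane of a poly-capillary
    element with focal distance z0 (mm)."""
    return 2.0 * z0 * critical_angle(energy)  # mm · mrad = μm


def separation_ok(a_out: float, waist: float) -> bool:
    """Whether beamlets separate through propagation: requires a_out > w
    (both μm).  Ties this apparatus's field of view (the waist) to its
    angular sampling in an inverse relationship."""
    return a_out > waist


def parallax_depth_bound(geometry: EmulationGeometry) -> float:
    """Depth change (mm) that shifts a point by one effective pixel between
    the extreme views — a parallax bound on depth resolution.

    Doubling it gives a depth-of-field figure: the axial interval over which
    a refocused point stays within one pixel of sharp.
    """
    theta = math.radians(geometry.angular_range())
    if theta <= 0:
        warnings.warn("zero angular range: depth is unconstrained")
        return math.inf
    return geometry.effective_pixel * 1e-3 / math.tan(theta)


# ---------------------------------------------------------------------------
# design file IO (JSON, with a design_type discriminator)
# ---------------------------------------------------------------------------

_DESIGN_TYPES = {"crystal": CrystalDesign, "polycap": PolycapDesign,
                 "lens": LensDesign}


def save_design(design, path) -> None:
    """Write a design to JSON with a ``design_type`` discriminator."""
    for name, cls in _DESIGN_TYPES.items():
        if isinstance(design, cls):
            break
    else:
        raise TypeError(f"not a design: {design!r}")
    payload: dict = {"design_type": name}
    for f in design.__dataclass_fields__:
        value = getattr(design, f)
        if isinstance(value, OpticalAxisFrame):
            value = {"z0": value.z0, "zsd": value.zsd}
        payload[f] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_design(path):
    """Load a crystal / polycap / lens design from JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        kind = payload.pop("design_type")
        cls = _DESIGN_TYPES[kind]
    except KeyError as exc:
        raise GeometryError(f"missing or unknown design_type in {path}") from exc
    if "frame" in payload:
        payload["frame"] = OpticalAxisFrame(**payload["frame"])
    if cls is CrystalDesign:
        payload["phi_centers"] = tuple(
            (float(p[0]), float(p[1])) for p in payload["phi_centers"]
        )
    return cls(**payload)
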