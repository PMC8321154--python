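"""Integration refocusing (shift-and-add) of light-fields.

Every view's PHI is reprojected onto a chosen depth plane through its own
source position and resampled onto the common focal-plane pixel grid; the
views are then averaged.  Structures lying at the chosen depth align across
views and stay sharp, everything else blurs — sweeping the depth produces a
focal stack, the input to both depth cues.

Geometry: a focal-plane point q at depth z maps, for the view with source S
and detector center D, to the detector position S + (q − S)·zsd/z.  At
z = z0 this reduces to q·zsd/z0 − D-centered pixel coordinates for every
view simultaneously (zero parallax at the focal plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import tifffile
from scipy.ndimage import map_coordinates

from .geometry import EmulationGeometry, parallax_depth_bound
from .lightfield import LightField

__all__ = [
    "FocalStack",
    "reproject_views",
    "refocus_plane",
    "focal_stack",
    "default_z_samples",
]


@dataclass(frozen=True)
class FocalStack:
    """Refocused images over an ascending depth sampling."""

    images: np.ndarray        # (nz, ny, nx)
    z_samples: np.ndarray     # mm, strictly increasing
    pixel_pitch: float        # mm at the focal plane (effective pixel)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_samples, dtype=float)
        if z.ndim != 1 or len(z) != self.images.shape[0]:
            raise ValueError("z_samples must match the stack depth axis")
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("z_samples must be strictly increasing")

    @property
    def n_planes(self) -> int:
        return self.images.shape[0]

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("stack", data=self.images, compression="gzip")
            fh.create_dataset("z_samples", data=np.asarray(self.z_samples))
            fh.attrs["pixel_pitch_mm"] = self.pixel_pitch

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.images.astype(np.float32))


def _focal_grid(geometry: EmulationGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Focal-plane sample coordinates (mm): (qx over columns, qy over rows)."""
    nx, ny = geometry.detector_pixels
    pitch = geometry.effective_pixel * 1e-3
    qx = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    qy = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    return qx, qy


def reproject_views(
    lf: LightField, z: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-view reprojections onto the plane at depth ``z``.

    Returns ``(values, weights)`` of shape (n_views, ny, nx): bilinear
    samples of each PHI at the detector position that the focal-plane grid
    point projects to, and a 0/1 weight marking samples inside the view's
    footprint.
    """
    frame = lf.geometry.frame
    if not (0.0 < z < frame.zsd):
        raise ValueError(f"refocus depth must lie in (0, zsd), got {z}")
    nx, ny = lf.geometry.detector_pixels
    pitch_det = lf.geometry.detector_pitch * 1e-3
    qx, qy = _focal_grid(lf.geometry)
    scale = frame.zsd / z
    vals = np.empty((lf.n_views, ny, nx))
    weights = np.empty_like(vals)
    for i, view in enumerate(lf.geometry.views):
        su, sv = view.source
        dx, dy = view.detector
        det_x = su + (qx - su) * scale                 # (nx,)
        det_y = sv + (qy - sv) * scale                 # (ny,)
        col = (det_x - dx) / pitch_det + (nx - 1) / 2.0
        row = (det_y - dy) / pitch_det + (ny - 1) / 2.0
        rows, cols = np.meshgrid(row, col, indexing="ij")
        vals[i] = map_coordinates(
            lf.images[i], [rows, cols], order=1, mode="constant", cval=0.0
        )
        inside = (
            (row >= 0)[:, None] & (row <= ny - 1)[:, None]
            & (col >= 0)[None, :] & (col <= nx - 1)[None, :]
        )
        weights[i] = inside
    return vals, weights


def refocus_plane(lf: LightField, z: float) -> np.ndarray:
    """Shift-and-add refocused image at depth ``z`` (mm): the unweighted
    average over views, excluding views whose footprint does not cover a
    pixel at large shifts."""
    vals, weights = reproject_views(lf, z)
    wsum = weights.sum(axis=0)
    out = np.zeros(wsum.shape)
    covered = wsum > 0
    out[covered] = (vals * weights).sum(axis=0)[covered] / wsum[covered]
    return out


def focal_stack(lf: LightField, z_samples) -> FocalStack:
    """Refocus at each sample of an ascending depth sweep."""
    z_samples = np.asarray(z_samples, dtype=float)
    images = np.stack([refocus_plane(lf, z) for z in z_samples])
    return FocalStack(
        images=images,
        z_samples=z_samples,
        pixel_pitch=lf.geometry.effective_pixel * 1e-3,
    )


def default_z_samples(
    geometry: EmulationGeometry,
    span_dof: float = 3.0,
    step_dof: float = 0.25,
) -> np.ndarray:
    """Depth sampling derived from the geometry's depth of field.

    Covers z0 ± ``span_dof``·DoF with step ``step_dof``·DoF, where
    DoF = 2× the one-pixel parallax bound.
    """
    dof = 2.0 * parallax_depth_bound(geometry)
    z0, zsd = geometry.frame.z0, geometry.frame.zsd
    half = span_dof * dof
    step = step_dof * dof
    n = int(np.floor(half / step))
    samples = z0 + step * np.arange(-n, n + 1)
    # wide-DoF geometries (few views, small angular range) can push the
    # sweep outside the physical (0, zsd) interval: keep the valid part
    samples = samples[(samples > 0.05 * z0) & (samples < zsd - 1e-6)]
    if len(samples) < 3:
        samples = np.linspace(0.5 * z0, min(1.5 * z0, zsd - 1e-6), 7)
    return samples
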