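"""The 4D light-field container and its on-disk formats.

A light-field here is the stack of pin-hole images (PHIs) acquired at every
emulated view, together with the matching open-beam (flat) images and the
scan geometry.  Images are stored as a flat ``(n_views, ny, nx)`` array in
the geometry's view order (row-major over ``(pv, pu)``); :meth:`as_grid`
exposes the 4D ``(Nv, Nu, ny, nx)`` layout when the views form a full grid.

Persistence: an HDF5 container (``images``, ``flats`` datasets plus
JSON-encoded geometry/settings/history attributes) and a tiled 2D TIFF
mosaic of the PHIs for quick visual inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import tifffile

from .geometry import EmulationGeometry

__all__ = ["LightField"]


@dataclass(frozen=True)
class LightField:
    """Per-view images plus flats and geometry metadata."""

    images: np.ndarray                 # (n_views, ny, nx)
    geometry: EmulationGeometry
    flats: np.ndarray | None = None    # (n_views, ny, nx)
    settings: dict = field(default_factory=dict)
    history: tuple[str, ...] = ()
    #: per-pixel noise-variance map of ``images`` (propagated through the
    #: pre-processing chain; None for noiseless data)
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.geometry.n_views
        nx, ny = self.geometry.detector_pixels
        if self.images.shape != (n, ny, nx):
            raise ValueError(
                f"images shape {self.images.shape} does not match geometry "
                f"({n} views of {ny}×{nx})"
            )
        if self.flats is not None and self.flats.shape != self.images.shape:
            raise ValueError("flats must match the images shape")

    @property
    def n_views(self) -> int:
        return self.images.shape[0]

    def with_images(self, images: np.ndarray, step: str,
                    variance: np.ndarray | None = None) -> "LightField":
        """New light-field with replaced pixel data (and optionally its
        propagated noise variance) plus an appended history entry."""
        if variance is None:
            variance = self.variance
        return replace(self, images=images, variance=variance,
                       history=self.history + (step,))

    def as_grid(self) -> np.ndarray:
        """4D view ``(Nv, Nu, ny, nx)``; requires a full odd view grid."""
        shape = self.geometry.grid_shape
        if shape is None:
            raise ValueError("views do not form a full grid")
        nv, nu = shape
        return self.images.reshape(nv, nu, *self.images.shape[1:])

    # -- persistence --------------------------------------------------------

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("images", data=self.images, compression="gzip")
            if self.flats is not None:
                fh.create_dataset("flats", data=self.flats, compression="gzip")
            if self.variance is not None:
                fh.create_dataset("variance", data=self.variance,
                                  compression="gzip")
            fh.attrs["geometry"] = json.dumps(self.geometry.to_dict())
            fh.attrs["settings"] = json.dumps(self.settings)
            fh.attrs["history"] = json.dumps(list(self.history))

    @classmethod
    def load_h5(cls, path) -> "LightField":
        with h5py.File(path, "r") as fh:
            images = fh["images"][()]
            flats = fh["flats"][()] if "flats" in fh else None
            variance = fh["variance"][()] if "variance" in fh else None
            geometry = EmulationGeometry.from_dict(
                json.loads(fh.attrs["geometry"])
            )
            settings = json.loads(fh.attrs["settings"])
            history = tuple(json.loads(fh.attrs["history"]))
        return cls(images=images, geometry=geometry, flats=flats,
                   settings=settings, history=history, variance=variance)

    def to_tiled_tiff(self, path) -> None:
        """Write the PHIs as one 2D mosaic (views tiled in grid order)."""
        grid = self.as_grid()
        nv, nu, ny, nx = grid.shape
        mosaic = grid.transpose(0, 2, 1, 3).reshape(nv * ny, nu * nx)
        tifffile.imwrite(path, mosaic.astype(np.float32))
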