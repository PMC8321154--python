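"""Digital phantoms with analytic ground truth.

Two phantom families emulate the published samples: a branch-like tree of
cylinder segments (vessel-like features, thicknesses 0.1–1.2 mm at the
emulation scale) and air bubbles suspended in a gel-filled cylindrical
container (sphere-like features).  Each phantom carries both a voxel grid
declaration and its analytic primitive list, so depth ground truth and object
footprints come from exact ray–primitive intersections rather than from the
voxelization.

Depth convention: all depths are the axial (z) distance from the source plane
in mm, matching the emulation frame; the ground-truth depth of a detector
pixel is the average of the z coordinates of the centers of all *object*
primitives on that pixel's line of sight (background primitives such as the
gel container are excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import h5py
import numpy as np
import pandas as pd

from .depthmap import DepthMap
from .geometry import EmulationGeometry
from .presets import Z0

__all__ = [
    "Primitive",
    "Phantom",
    "AttenuationVolume",
    "make_branch_phantom",
    "make_bubble_phantom",
    "make_crossing_phantom",
    "voxelize",
    "ground_truth_depthmap",
    "central_view_rays",
    "primitive_hit_mask",
]


class PhantomError(ValueError):
    """Phantom construction or voxelization failure."""


@dataclass(frozen=True)
class Primitive:
    """One analytic solid: a sphere or a finite cylinder segment.

    ``attenuation`` is a signed delta (mm⁻¹) added to the composed volume;
    air bubbles in gel carry a negative delta.  ``role`` distinguishes the
    imaged objects from background structures (e.g. the gel container) that
    do not count as depth-map targets.
    """

    kind: Literal["sphere", "cylinder"]
    p0: tuple[float, float, float]       # sphere center, or segment start (mm)
    radius: float                        # mm
    attenuation: float                   # mm⁻¹ delta
    p1: tuple[float, float, float] | None = None  # segment end (cylinder only)
    role: Literal["object", "background"] = "object"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise PhantomError("primitive radius must be positive")
        if self.kind == "cylinder" and self.p1 is None:
            raise PhantomError("cylinder segment needs an end point p1")

    @property
    def center(self) -> np.ndarray:
        if self.kind == "sphere":
            return np.asarray(self.p0, dtype=float)
        return 0.5 * (np.asarray(self.p0, float) + np.asarray(self.p1, float))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners (mm) of an axis-aligned bounding box."""
        if self.kind == "sphere":
            c = np.asarray(self.p0, float)
            return c - self.radius, c + self.radius
        a, b = np.asarray(self.p0, float), np.asarray(self.p1, float)
        axis = b - a
        bhat = axis / np.linalg.norm(axis)
        # exact per-axis half-width of the end-cap disks
        pad = self.radius * np.sqrt(np.clip(1.0 - bhat**2, 0.0, 1.0))
        lo = np.minimum(a, b) - pad
        hi = np.maximum(a, b) + pad
        return lo, hi

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean indicator at ``points`` (..., 3) in mm."""
        pts = np.asarray(points, dtype=float)
        if self.kind == "sphere":
            d2 = np.sum((pts - np.asarray(self.p0)) ** 2, axis=-1)
            return d2 <= self.radius**2
        a = np.asarray(self.p0, float)
        b = np.asarray(self.p1, float)
        axis = b - a
        length2 = float(axis @ axis)
        rel = pts - a
        s = rel @ axis / length2                  # axial parameter in [0, 1]
        perp = rel - s[..., None] * axis
        d2 = np.sum(perp**2, axis=-1)
        return (d2 <= self.radius**2) & (s >= 0.0) & (s <= 1.0)


@dataclass(frozen=True)
class Phantom:
    """Voxel grid declaration plus analytic primitive list.

    ``origin`` is the lower corner (mm) of the grid; voxel centers sit at
    ``origin + (i + 0.5) * voxel_size``.  The grid is placed so the volume
    straddles the focal plane of the emulation frame.
    """

    shape: tuple[int, int, int]          # (nx, ny, nz)
    voxel_size: float                    # mm, isotropic
    origin: tuple[float, float, float]   # mm
    primitives: tuple[Primitive, ...]
    background_mu: float = 0.0           # mm⁻¹ everywhere before composition
    meta: dict = field(default_factory=dict)

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        hi = lo + np.asarray(self.shape, float) * self.voxel_size
        return lo, hi

    @property
    def objects(self) -> tuple[Primitive, ...]:
        return tuple(p for p in self.primitives if p.role == "object")

    def primitives_table(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.primitives):
            rows.append(
                {
                    "id": i,
                    "kind": p.kind,
                    "role": p.role,
                    "x0": p.p0[0], "y0": p.p0[1], "z0": p.p0[2],
                    "x1": p.p1[0] if p.p1 else np.nan,
                    "y1": p.p1[1] if p.p1 else np.nan,
                    "z1": p.p1[2] if p.p1 else np.nan,
                    "radius_mm": p.radius,
                    "attenuation_mm^-1": p.attenuation,
                }
            )
        return pd.DataFrame(rows)

    def to_hdf5(self, path, include_volume: bool = True) -> None:
        with h5py.File(path, "w") as fh:
            if include_volume:
                fh.create_dataset("mu", data=voxelize(self).mu, compression="gzip")
            fh.attrs["voxel_size_mm"] = self.voxel_size
            fh.attrs["origin_mm"] = np.asarray(self.origin)
            fh.attrs["shape"] = np.asarray(self.shape)
            fh.attrs["background_mu"] = self.background_mu
            fh.attrs["meta"] = json.dumps(self.meta)
            table = self.primitives_table()
            for col in table.columns:
                data = table[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                fh.create_dataset(f"primitives/{col}", data=data)


@dataclass(frozen=True)
class AttenuationVolume:
    """Voxelized attenuation map μ (mm⁻¹) on a regular grid."""

    mu: np.ndarray                       # float32 (nx, ny, nz)
    origin: tuple[float, float, float]   # mm, lower corner
    voxel_size: float                    # mm

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        hi = lo + np.asarray(self.mu.shape, float) * self.voxel_size
        return lo, hi


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _grid_for_extent(center, half_sizes, voxel_size):
    half = np.asarray(half_sizes, float)
    center = np.asarray(center, float)
    shape = tuple(int(np.ceil(2 * h / voxel_size)) for h in half)
    origin = tuple(center - np.asarray(shape) * voxel_size / 2.0)
    return shape, origin


def make_branch_phantom(
    seed: int,
    n_segments: int = 40,
    thickness_range: tuple[float, float] = (0.1, 1.2),
    extent: tuple[float, float, float] = (7.0, 7.0, 25.0),
    center: tuple[float, float, float] = (0.0, 0.0, Z0),
    attenuation: float = 0.06,
    voxel_size: float = 0.15,
) -> Phantom:
    """Random connected tree of cylinder segments (a vessel-like branch).

    The tree grows from a single root; each child segment starts at its
    parent's end point, thicknesses shrink from ``thickness_range[1]`` at the
    root toward ``thickness_range[0]`` at the tips, and all segments are kept
    inside ``extent`` (half-sizes, mm, centered on ``center``).  Deterministic
    for a fixed seed.
    """
    t_min, t_max = thickness_range
    if not (0.05 <= t_min <= t_max <= 2.0):
        raise PhantomError("thickness_range must lie within [0.05, 2.0] mm")
    if n_segments < 1:
        raise PhantomError("need at least one segment")
    half = np.asarray(extent, float)
    if np.min(half) < 2.0 * t_max:
        raise PhantomError("extent too small to host the tree")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, float)
    lo, hi = center - half + t_max, center + half - t_max

    def clamp(p):
        return np.clip(p, lo, hi)

    # expected tree depth if every tip branched once per level
    max_level = max(2, int(np.ceil(np.log2(n_segments + 1))))
    root = clamp(center + np.array([0.0, -0.8 * half[1], 0.0]))
    root_dir = np.array([0.0, 1.0, 0.0])
    tips = [(root, root_dir, 0)]  # (position, direction, level)
    segments: list[Primitive] = []
    seg_len = 0.45 * float(np.min(half))
    while len(segments) < n_segments and tips:
        pos, direction, level = tips.pop(0)
        # stronger axial wander: the slab is deep (±extent_z) but narrow
        # transversely, and depth spread is what makes the tree a useful
        # depth-recovery target
        jitter = rng.normal(size=3) * np.array([0.35, 0.35, 0.9])
        d = direction + jitter
        d /= np.linalg.norm(d)
        length = seg_len * rng.uniform(0.7, 1.3)
        end = clamp(pos + length * d)
        frac = min(level / max_level, 1.0)
        radius = 0.5 * (t_max + frac * (t_min - t_max))
        radius = float(np.clip(radius, t_min / 2.0, t_max / 2.0))
        if np.linalg.norm(end - pos) < 1e-6:
            continue
        segments.append(
            Primitive("cylinder", tuple(pos), radius, attenuation, tuple(end))
        )
        new_dir = (end - pos) / np.linalg.norm(end - pos)
        n_children = 2 if rng.random() < 0.4 else 1
        for _ in range(n_children):
            tips.append((end, new_dir, level + 1))
    shape, origin = _grid_for_extent(center, half, voxel_size)
    return Phantom(
        shape=shape,
        voxel_size=voxel_size,
        origin=origin,
        primitives=tuple(segments),
        meta={"family": "branch", "seed": int(seed),
              "thickness_range_mm": list(thickness_range)},
    )


def make_bubble_phantom(
    seed: int,
    n_bubbles: int = 14,
    radius_range: tuple[float, float] = (1.0, 4.0),
    container_radius: float = 13.0,
    container_half_length: float = 27.0,
    depth_span: float = 20.0,
    placement_radius: float = 7.5,
    center_z: float = Z0,
    gel_mu: float = 0.02,
    voxel_size: float = 0.15,
) -> Phantom:
    """Air bubbles in a gel-filled cylinder.

    The container is a finite cylinder of gel (attenuation ``gel_mu``)
    oriented along the optical axis so bubble depths can span
    ``center_z ± depth_span`` while staying inside the transverse field of
    view; its radius exceeds the corner distance of the reference field of
    view so the sharp tube-wall edge stays out of frame (only the smooth
    container signal enters the images, which background subtraction
    removes).  Bubbles are placed within ``placement_radius`` of the axis.
    Bubble radii span ``radius_range`` with a distribution skewed toward
    small bubbles (as in real gas-in-gel populations); placement is
    rejection sampling that enforces both 3-D non-overlap and limited
    overlap of the central-view projections, so individual bubbles remain
    discernible in the images (the regime in which a per-bubble depth
    comparison is meaningful).  Deterministic for fixed seed.
    """
    r_min, r_max = radius_range
    if n_bubbles < 1:
        raise PhantomError("need at least one bubble")
    if r_max >= min(container_radius, placement_radius):
        raise PhantomError("bubbles must fit inside the container")
    rng = np.random.default_rng(seed)
    margin = 0.1  # mm, minimum gap between bubble surfaces
    placed: list[tuple[np.ndarray, float]] = []
    max_tries = 2000 * n_bubbles
    tries = 0
    while len(placed) < n_bubbles and tries < max_tries:
        tries += 1
        r = r_min + (r_max - r_min) * rng.beta(1.0, 3.0)
        rho_max = min(container_radius, placement_radius) - r - margin
        rho = rho_max * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        z_half = min(depth_span, container_half_length - r - margin)
        c = np.array(
            [rho * np.cos(phi), rho * np.sin(phi),
             center_z + rng.uniform(-z_half, z_half)]
        )
        separated = all(
            np.linalg.norm(c - c2) > r + r2 + margin
            and np.hypot(c[0] - c2[0], c[1] - c2[1]) > 0.7 * (r + r2) + 0.3
            for c2, r2 in placed
        )
        if separated:
            placed.append((c, r))
    if len(placed) < n_bubbles:
        raise PhantomError(
            f"could only place {len(placed)} of {n_bubbles} bubbles without "
            "overlap; reduce n_bubbles or radii"
        )
    container = Primitive(
        "cylinder",
        (0.0, 0.0, center_z - container_half_length),
        container_radius,
        gel_mu,
        (0.0, 0.0, center_z + container_half_length),
        role="background",
    )
    bubbles = tuple(
        Primitive("sphere", tuple(c), r, -gel_mu) for c, r in placed
    )
    half = np.array(
        [container_radius + 1.0, container_radius + 1.0,
         container_half_length + 1.0]
    )
    shape, origin = _grid_for_extent((0.0, 0.0, center_z), half, voxel_size)
    return Phantom(
        shape=shape,
        voxel_size=voxel_size,
        origin=origin,
        primitives=(container,) + bubbles,
        meta={"family": "bubbles", "seed": int(seed), "gel_mu": gel_mu,
              "radius_range_mm": list(radius_range),
              "depth_span_mm": depth_span},
    )


def make_crossing_phantom(
    z_offsets: tuple[float, float] = (-10.0, 10.0),
    radius: float = 0.5,
    center_z: float = Z0,
    attenuation: float = 0.06,
    half_span: float = 6.0,
    voxel_size: float = 0.15,
) -> Phantom:
    """Two straight branch segments at different depths that cross in the
    central view — the fixture for the semi-transparency limitation (a
    single-depth estimator averages the two depths at overlap pixels)."""
    za, zb = (center_z + o for o in z_offsets)
    a = Primitive(
        "cylinder", (-half_span, 0.0, za), radius, attenuation,
        (half_span, 0.0, za),
    )
    b = Primitive(
        "cylinder", (0.0, -half_span, zb), radius, attenuation,
        (0.0, half_span, zb),
    )
    half = np.array([half_span + 1.0, half_span + 1.0,
                     max(abs(z_offsets[0]), abs(z_offsets[1])) + 3.0])
    shape, origin = _grid_for_extent((0.0, 0.0, center_z), half, voxel_size)
    return Phantom(
        shape=shape, voxel_size=voxel_size, origin=origin,
        primitives=(a, b), meta={"family": "crossing"},
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize(phantom: Phantom) -> AttenuationVolume:
    """Compose the attenuation volume: background plus primitive deltas,
    anti-aliased with 2× supersampling (8 offset indicator evaluations per
    voxel), clipped at zero."""
    nx, ny, nz = phantom.shape
    vs = phantom.voxel_size
    origin = np.asarray(phantom.origin, float)
    lo_grid, hi_grid = phantom.extent
    mu = np.full(phantom.shape, phantom.background_mu, dtype=np.float32)
    offsets = [-0.25 * vs, 0.25 * vs]
    for prim in phantom.primitives:
        lo, hi = prim.bounding_box()
        if np.any(hi < lo_grid - 1e-9) or np.any(lo > hi_grid + 1e-9):
            raise PhantomError(f"primitive lies outside the grid: {prim}")
        if np.any(lo < lo_grid - 1e-6) or np.any(hi > hi_grid + 1e-6):
            raise PhantomError(
                f"grid extent does not cover primitive: {prim}"
            )
        i_lo = np.maximum(((lo - origin) / vs).astype(int) - 1, 0)
        i_hi = np.minimum(((hi - origin) / vs).astype(int) + 2,
                          np.array([nx, ny, nz]))
        xs = origin[0] + (np.arange(i_lo[0], i_hi[0]) + 0.5) * vs
        ys = origin[1] + (np.arange(i_lo[1], i_hi[1]) + 0.5) * vs
        zs = origin[2] + (np.arange(i_lo[2], i_hi[2]) + 0.5) * vs
        frac = np.zeros((len(xs), len(ys), len(zs)), dtype=np.float32)
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    pts = np.stack(
                        np.meshgrid(xs + dx, ys + dy, zs + dz, indexing="ij"),
                        axis=-1,
                    )
                    frac += prim.contains(pts)
        frac /= len(offsets) ** 3
        mu[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] += (
            prim.attenuation * frac
        )
    np.clip(mu, 0.0, None, out=mu)
    return AttenuationVolume(mu=mu, origin=tuple(origin), voxel_size=vs)


# ---------------------------------------------------------------------------
# analytic rays: ground truth and footprints
# ---------------------------------------------------------------------------

def central_view_rays(geometry: EmulationGeometry) -> np.ndarray:
    """Unit direction (ny, nx, 3) of the ray from the central source S(0,0)
    through each central-view detector pixel center."""
    nx, ny = geometry.detector_pixels
    pitch = geometry.detector_pitch * 1e-3  # mm
    view = geometry.views[geometry.central_index]
    dx, dy = view.detector
    xs = dx + (np.arange(nx) - (nx - 1) / 2.0) * pitch
    ys = dy + (np.arange(ny) - (ny - 1) / 2.0) * pitch
    su, sv = view.source
    dirs = np.empty((ny, nx, 3), dtype=float)
    dirs[..., 0] = xs[None, :] - su
    dirs[..., 1] = ys[:, None] - sv
    dirs[..., 2] = geometry.frame.zsd
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return dirs


def primitive_hit_mask(
    prim: Primitive, dirs: np.ndarray, origin=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Whether the rays ``origin + t·dirs`` (t > 0) intersect the primitive.

    Exact for spheres and capped cylinder segments.
    """
    o = np.asarray(origin, float)
    d = np.asarray(dirs, float)
    if prim.kind == "sphere":
        c = np.asarray(prim.p0, float) - o
        t_ca = d @ c
        d2 = c @ c - t_ca**2
        return (d2 <= prim.radius**2) & (t_ca > 0)
    a = np.asarray(prim.p0, float)
    b = np.asarray(prim.p1, float)
    axis = b - a
    length = float(np.linalg.norm(axis))
    bhat = axis / length
    w = o - a
    d_par = d @ bhat
    d_perp = d - d_par[..., None] * bhat
    w_par = float(w @ bhat)
    w_perp = w - w_par * bhat
    qa = np.sum(d_perp**2, axis=-1)
    qb = 2.0 * (d_perp @ w_perp)
    qc = float(w_perp @ w_perp) - prim.radius**2
    disc = qb**2 - 4.0 * qa * qc
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
        t_lo = (-qb - sqrt_disc) / (2.0 * qa)
        t_hi = (-qb + sqrt_disc) / (2.0 * qa)
        # rays (near-)parallel to the axis: inside iff qc <= 0 for all t
        parallel = qa < 1e-14
        t_lo = np.where(parallel, -np.inf, t_lo)
        t_hi = np.where(parallel, np.inf, t_hi)
        radial_ok = np.where(parallel, qc <= 0.0, disc >= 0.0)
        # axial constraint 0 <= w_par + t*d_par <= length, as a t interval
        s_lo = (0.0 - w_par) / d_par
        s_hi = (length - w_par) / d_par
        ax_lo = np.minimum(s_lo, s_hi)
        ax_hi = np.maximum(s_lo, s_hi)
        axial_flat = np.abs(d_par) < 1e-14
        ax_lo = np.where(axial_flat, -np.inf, ax_lo)
        ax_hi = np.where(axial_flat, np.inf, ax_hi)
        axial_ok = np.where(axial_flat, (w_par >= 0) & (w_par <= length), True)
    t_enter = np.maximum(np.maximum(t_lo, ax_lo), 0.0)
    t_exit = np.minimum(t_hi, ax_hi)
    return radial_ok & axial_ok & (t_enter <= t_exit)


def ground_truth_depthmap(
    phantom: Phantom, geometry: EmulationGeometry
) -> DepthMap:
    """Analytic depth map of the central view.

    For each central-view pixel, cast the ray from S(0,0) through the pixel
    center; the depth is the mean z of the centers of all *object* primitives
    the ray intersects; pixels hitting nothing are invalid.
    """
    dirs = central_view_rays(geometry)
    ny, nx = dirs.shape[:2]
    depth_sum = np.zeros((ny, nx), dtype=float)
    count = np.zeros((ny, nx), dtype=int)
    for prim in phantom.objects:
        hit = primitive_hit_mask(prim, dirs)
        depth_sum += hit * prim.center[2]
        count += hit
    valid = count > 0
    depth = np.where(valid, depth_sum / np.maximum(count, 1), np.nan)
    confidence = valid.astype(float)
    return DepthMap(depth=depth, confidence=confidence, valid=valid,
                    meta={"source": "analytic-ground-truth"})
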