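"""Reconstruction of parallel sagittal planes from a para-sagittal fan sweep.

A side-fire probe acquires 2D frames rotated about the probe's long axis.
Each frame is placed in 3D using its rotation angle and the fixed
transducer-to-first-pixel-row offset, samples are binned onto parallel
planes spaced along the left-right axis, and remaining holes are filled by
per-plane gridded linear interpolation.

Axis convention (used by every module in this package):

* ``x`` — probe long axis (along-probe direction of each frame),
* ``y`` — left-right plane-stacking axis,
* ``z`` — distance from the probe axis (depth).

A frame at rotation angle ``theta`` maps pixel ``(u, v)`` (``u`` = depth row,
``v`` = along-probe column) to world coordinates::

    x = v * sv
    y = (u * su + offset) * sin(theta)
    z = (u * su + offset) * cos(theta)

where ``(su, sv)`` are the in-plane pixel spacings in mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

logger = logging.getLogger(__name__)

DEFAULT_OFFSET_MM = 2.0
DEFAULT_PLANE_SPACING_MM = 1.0
DEFAULT_BIN_HALFWIDTH_MM = 0.5
BACKGROUND_VALUE = 0.0


@dataclass(frozen=True)
class FanFrame:
    """One 2D frame of a rotational sweep.

    ``pixels[u, v]``: ``u`` indexes depth (away from the probe), ``v`` indexes
    the along-probe direction. ``in_plane_spacing`` is ``(su, sv)`` in mm.
    """

    pixels: np.ndarray
    angle_deg: float
    in_plane_spacing: tuple[float, float]
    offset_mm: float = DEFAULT_OFFSET_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        object.__setattr__(self, "pixels", px)
        su, sv = self.in_plane_spacing
        if su <= 0 or sv <= 0:
            raise ValueError("in-plane spacing must be positive")
        if self.offset_mm < 0:
            raise ValueError("offset_mm must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FanSweep:
    """Ordered frames of one rotational sweep; all frames share shape and spacing."""

    frames: tuple[FanFrame, ...]
    monotone: bool = True

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("sweep must contain at least one frame")
        ref = frames[0]
        for f in frames[1:]:
            if f.shape != ref.shape:
                raise ValueError("all frames must share the same pixel shape")
            if f.in_plane_spacing != ref.in_plane_spacing:
                raise ValueError("all frames must share the same in-plane spacing")
            if f.offset_mm != ref.offset_mm:
                raise ValueError("all frames must share the same offset")
        object.__setattr__(self, "frames", frames)
        if self.monotone and len(frames) > 1:
            ang = np.array([f.angle_deg for f in frames])
            d = np.diff(ang)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("angles must be strictly monotone")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([f.angle_deg for f in self.frames])


@dataclass
class ImageVolume:
    """3D voxel grid; ``voxels[ix, iy, iz]`` at ``origin + (ix, iy, iz) * spacing``."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background: float = BACKGROUND_VALUE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinates of voxel centers in mm."""
        return tuple(
            self.origin[k] + np.arange(self.shape[k]) * self.spacing[k]
            for k in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) mm points to fractional voxel indices."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)


def frame_pixel_to_world(
    frame: FanFrame, u: np.ndarray | float, v: np.ndarray | float
) -> np.ndarray:
    """Map frame pixel indices (fractional allowed) to 3D world mm coordinates.

    Returns an array of shape ``(..., 3)`` with columns (x, y, z).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = frame.shape
    if np.any(u < 0) or np.any(u > nu - 1) or np.any(v < 0) or np.any(v > nv - 1):
        raise IndexError("pixel index outside frame bounds")
    su, sv = frame.in_plane_spacing
    r = u * su + frame.offset_mm
    theta = np.deg2rad(frame.angle_deg)
    x = v * sv
    y = r * np.sin(theta)
    z = r * np.cos(theta)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def _fill_plane_holes(
    plane: np.ndarray,
    filled: np.ndarray,
    x_coords: np.ndarray,
    z_coords: np.ndarray,
    background: float,
) -> np.ndarray:
    """Fill unfilled voxels of one plane by 2D linear interpolation.

    Interpolation is restricted to the convex hull of contributed samples;
    everything outside the hull keeps the background value.
    """
    if filled.all():
        return plane
    n_filled = int(filled.sum())
    if n_filled < 3:
        return plane
    ix, iz = np.nonzero(filled)
    pts = np.column_stack([x_coords[ix], z_coords[iz]])
    vals = plane[filled]
    try:
        interp = LinearNDInterpolator(pts, vals, fill_value=np.nan)
    except Exception:  # degenerate (e.g. collinear) sample set
        return plane
    hx, hz = np.nonzero(~filled)
    est = interp(np.column_stack([x_coords[hx], z_coords[hz]]))
    out = plane.copy()
    good = np.isfinite(est)
    out[hx[good], hz[good]] = est[good]
    out[hx[~good], hz[~good]] = background
    return out


def reconstruct_volume(
    sweep: FanSweep,
    plane_spacing_mm: float = DEFAULT_PLANE_SPACING_MM,
    bin_halfwidth_mm: float = DEFAULT_BIN_HALFWIDTH_MM,
    fill_holes: bool = True,
    background: float = BACKGROUND_VALUE,
) -> ImageVolume:
    """Reconstruct parallel planes along y from a rotational fan sweep.

    Every frame pixel is placed in 3D by :func:`frame_pixel_to_world`, assigned
    to the nearest output plane when it lies within ``bin_halfwidth_mm`` of it,
    and voxel values are the mean of all samples landing in each voxel bin.
    Remaining holes inside the sampled support of each plane are filled by
    gridded linear interpolation; voxels outside the support keep
    ``background``.
    """
    if plane_spacing_mm <= 0 or bin_halfwidth_mm <= 0:
        raise ValueError("plane spacing and bin halfwidth must be positive")
    ref = sweep.frames[0]
    nu, nv = ref.shape
    su, sv = ref.in_plane_spacing

    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    angles = sweep.angles_deg
    theta = np.deg2rad(angles)
    r = uu.ravel() * su + ref.offset_mm  # per-pixel radial depth, shared by frames

    y_all = np.outer(np.sin(theta), r)  # (n_frames, n_pixels)
    z_all = np.outer(np.cos(theta), r)

    j_all = np.rint(y_all / plane_spacing_mm).astype(int)
    keep = np.abs(y_all - j_all * plane_spacing_mm) <= bin_halfwidth_mm

    if not keep.any():
        raise ValueError("no samples land within any plane bin")
    j_min, j_max = int(j_all[keep].min()), int(j_all[keep].max())
    ny = j_max - j_min + 1
    if ny == 1 and len(sweep) > 1:
        warnings.warn("sweep collapses to a single reconstructed plane", stacklevel=2)

    z_flat = z_all[keep]
    z0 = np.floor(z_flat.min() / su) * su
    iz_all = np.rint((z_all - z0) / su).astype(int)
    nz = int(iz_all[keep].max()) + 1

    ix = np.broadcast_to(vv.ravel(), j_all.shape)[keep]
    iy = j_all[keep] - j_min
    iz = iz_all[keep]
    values = np.stack([f.pixels.ravel() for f in sweep.frames])[keep]

    acc = np.zeros((nv, ny, nz))
    cnt = np.zeros((nv, ny, nz))
    np.add.at(acc, (ix, iy, iz), values)
    np.add.at(cnt, (ix, iy, iz), 1.0)
    filled = cnt > 0
    voxels = np.full((nv, ny, nz), float(background))
    voxels[filled] = acc[filled] / cnt[filled]

    if fill_holes:
        x_coords = np.arange(nv) * sv
        z_coords = z0 + np.arange(nz) * su
        for j in range(ny):
            voxels[:, j, :] = _fill_plane_holes(
                voxels[:, j, :], filled[:, j, :], x_coords, z_coords, background
            )

    logger.info(
        "reconstructed %d planes (y = %g..%g mm) from %d frames",
        ny, j_min * plane_spacing_mm, j_max * plane_spacing_mm, len(sweep),
    )
    return ImageVolume(
        voxels=voxels,
        spacing=(sv, plane_spacing_mm, su),
        origin=(0.0, j_min * plane_spacing_mm, z0),
        background=float(background),
        metadata={
            "plane_spacing_mm": plane_spacing_mm,
            "bin_halfwidth_mm": bin_halfwidth_mm,
            "n_frames": len(sweep),
            "axes": "x=probe long axis, y=left-right, z=depth from probe axis",
        },
    )
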