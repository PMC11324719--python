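"""2D slice registration of MRI to whole-mount pathology via capsule contours.

Each matched (MRI slice, WM slide) pair is registered in two stages: a
least-squares similarity transform (scale + rotation + translation, fitted by
orthogonal Procrustes on corresponded capsule points) followed by a
thin-plate-spline warp on a subset of the corresponded points. Contour
correspondence uses equal-arc-length resampling anchored at the
posterior-most vertex. Registration quality is scored as the dice overlap of
the transformed transition zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .landmark_registration import CompositeTransform, fit_tps
from .raster import DEFAULT_PIXEL_MM, grid_for_polygons, polygon_mask

logger = logging.getLogger(__name__)

CONTOUR_KINDS = ("capsule", "transition_zone")


@dataclass(frozen=True)
class CapsuleContour:
    """Closed simple 2D polygon (mm) outlining the capsule or transition zone."""

    slice_id: str
    kind: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 two-dimensional vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]  # closure is implied; drop a repeated last vertex
        if v.shape[0] < 3:
            raise ValueError("contour needs >= 3 distinct vertices")
        if not Polygon(v).is_valid:
            raise ValueError(f"contour {self.slice_id!r}/{self.kind} self-intersects")
        if self.kind not in CONTOUR_KINDS:
            raise ValueError(f"kind must be one of {CONTOUR_KINDS}")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class SimilarityTransform2D:
    """p -> scale * R(rotation_deg) @ p + translation; reflection disallowed."""

    scale: float
    rotation_deg: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return self.scale * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.matrix.T + self.translation


@dataclass(frozen=True)
class SlideCorrespondence:
    """Human-curated matching of WM slides to MRI slice indices."""

    entries: tuple  # ordered (wm_slide_id, mri_slice_index) pairs
    mri_slice_spacing_mm: float = 1.5
    wm_thickness_mm: float = 4.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", tuple((str(s), int(i)) for s, i in self.entries)
        )


@dataclass
class CorrespondenceReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_slide_correspondence(corr: SlideCorrespondence) -> CorrespondenceReport:
    """Check that slide-to-slice matching is monotone, unique and evenly stepped.

    Consecutive matched MRI indices must differ by
    round(wm_thickness / mri_spacing) ± 1 (one WM slide per
    thickness-equivalent block of MRI frames).
    """
    if not corr.entries:
        raise ValueError("empty slide correspondence")
    report = CorrespondenceReport()
    indices = [i for _, i in corr.entries]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        report.violations.append(f"duplicate MRI slice indices: {dupes}")
    expected = round(corr.wm_thickness_mm / corr.mri_slice_spacing_mm)
    for (sid_a, ia), (sid_b, ib) in zip(corr.entries, corr.entries[1:]):
        step = ib - ia
        if step <= 0:
            report.violations.append(
                f"non-monotone MRI indices between {sid_a!r} ({ia}) and {sid_b!r} ({ib})"
            )
        elif abs(step - expected) > 1:
            report.violations.append(
                f"spacing between {sid_a!r} and {sid_b!r} is {step} MRI frames; "
                f"expected {expected} ± 1"
            )
    return report


# ---------------------------------------------------------------------------
# contour correspondence


def _resample_closed(vertices: np.ndarray, n_points: int, start_at: np.ndarray) -> np.ndarray:
    """Resample a closed polygon to n equal-arc-length points starting near start_at."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    # arc-length position of the anchor: project onto the polygon densely
    dense_s = np.linspace(0.0, total, 4096, endpoint=False)
    dense = np.column_stack(
        [np.interp(dense_s, cum, v[:, 0]), np.interp(dense_s, cum, v[:, 1])]
    )
    s0 = dense_s[np.argmin(np.linalg.norm(dense - start_at, axis=1))]
    s = (s0 + np.arange(n_points) * total / n_points) % total
    return np.column_stack([np.interp(s, cum, v[:, 0]), np.interp(s, cum, v[:, 1])])


def _oriented_ccw(vertices: np.ndarray) -> np.ndarray:
    v = np.vstack([vertices, vertices[:1]])
    area2 = np.sum(v[:-1, 0] * v[1:, 1] - v[1:, 0] * v[:-1, 1])
    return vertices if area2 > 0 else vertices[::-1]


def _posterior_anchor(vertices: np.ndarray) -> np.ndarray:
    """Posterior-most boundary point: minimum second coordinate."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    dense_s = np.linspace(0.0, cum[-1], 4096, endpoint=False)
    dense = np.column_stack(
        [np.interp(dense_s, cum, v[:, 0]), np.interp(dense_s, cum, v[:, 1])]
    )
    return dense[np.argmin(dense[:, 1])]


def correspond_contours(
    fixed: CapsuleContour, moving: CapsuleContour, n_points: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Index-matched point pairs on two capsule contours.

    Each contour is oriented counterclockwise, resampled to ``n_points``
    equal-arc-length vertices, and anchored at its posterior-most (minimum
    second coordinate) boundary point; correspondence is by index.
    Returns ``(fixed_points, moving_points)``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    out = []
    for contour in (fixed, moving):
        verts = _oriented_ccw(contour.vertices)
        anchor = _posterior_anchor(verts)
        out.append(_resample_closed(verts, n_points, anchor))
    return out[0], out[1]


def fit_similarity(
    moving_points: np.ndarray, fixed_points: np.ndarray
) -> SimilarityTransform2D:
    """Closed-form least-squares similarity (Procrustes/Umeyama, no reflection)."""
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    if mov.shape != fix.shape or len(mov) < 2:
        raise ValueError("need >= 2 matched point pairs of equal shape")
    cm, cf = mov.mean(axis=0), fix.mean(axis=0)
    m0, f0 = mov - cm, fix - cf
    var_m = (m0**2).sum() / len(mov)
    if var_m < 1e-12:
        raise ValueError("moving points are (nearly) coincident")
    cov = f0.T @ m0 / len(mov)
    U, S, Vt = np.linalg.svd(cov)
    D = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        D[1, 1] = -1.0
    R = U @ D @ Vt
    scale = float(np.trace(np.diag(S) @ D) / var_m)
    if scale <= 0:
        raise ValueError("degenerate similarity fit")
    rotation_deg = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    translation = cf - scale * R @ cm
    return SimilarityTransform2D(
        scale=scale, rotation_deg=rotation_deg, translation=translation
    )


def register_slice(
    moving_capsule: CapsuleContour,
    fixed_capsule: CapsuleContour,
    n_points: int = 64,
    tps_control_stride: int = 4,
    regularization: float = 0.0,
) -> CompositeTransform:
    """Similarity then TPS registration of one MRI slice onto its WM slide.

    The similarity is fitted on all corresponded capsule points. Because the
    posterior anchor can slide along the boundary under deformation, circular
    shifts of the arc-length correspondence within a +-22.5 degree window of
    the anchor are tried and the shift with the smallest similarity residual
    is kept; the window keeps near-symmetric (elliptical) capsules from
    sliding to a spurious tangential alignment. The TPS is then fitted on
    every ``tps_control_stride``-th pair of the similarity residual to avoid
    overfitting capsule noise.
    """
    fixed_pts, moving_pts = correspond_contours(fixed_capsule, moving_capsule, n_points)
    window = max(1, n_points // 16)
    best = None
    for shift in range(-window, window + 1):
        rolled = np.roll(moving_pts, -shift, axis=0)
        cand = fit_similarity(rolled, fixed_pts)
        cost = ((cand.apply(rolled) - fixed_pts) ** 2).sum()
        if best is None or cost < best[0]:
            best = (cost, rolled, cand)
    _, moving_pts, sim = best
    moved = sim.apply(moving_pts)
    stride = max(1, int(tps_control_stride))
    tps = fit_tps(
        moved[::stride], fixed_pts[::stride], dimension=2, regularization=regularization
    )
    return CompositeTransform((sim, tps))


def transition_zone_dice(
    fixed_tz: CapsuleContour,
    moving_tz: CapsuleContour,
    transform=None,
    pixel_mm: float = DEFAULT_PIXEL_MM,
) -> float:
    """Dice overlap of the two transition zones after transforming the moving one."""
    moving_verts = moving_tz.vertices
    if transform is not None:
        moving_verts = transform.apply(moving_verts)
    grid = grid_for_polygons([fixed_tz.vertices, moving_verts], pixel_mm=pixel_mm)
    a = polygon_mask(fixed_tz.vertices, grid)
    b = polygon_mask(moving_verts, grid)
    if not a.any() or not b.any():
        raise ValueError("a transition zone rasterized to an empty region")
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
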