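"""Carry reviewer annotations from native frames into WM slide coordinates.

Annotation polygons drawn on native fan-sweep frames are sampled into 3D
point-clouds (using the same geometry as image reconstruction), pushed
through the stored 3D landmark warp, assigned to matched WM slides by their
axial coordinate, warped by each slide's 2D capsule registration, and
finally clustered with DBSCAN into outlined regions of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path
from shapely.geometry import MultiPoint, Polygon
from sklearn.cluster import DBSCAN

from .fan_reconstruction import FanFrame, frame_pixel_to_world
from .landmark_registration import apply_transform
from .raster import Grid2D, polygon_mask

logger = logging.getLogger(__name__)

MODALITIES = ("microUS", "pMRI", "rMRI")
MAX_ANNOTATIONS_PER_REVIEWER = 2  # microUS reviewers mark up to two lesions/subject


@dataclass(frozen=True)
class Provenance:
    reviewer_id: str
    modality: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


@dataclass(frozen=True)
class AnnotationPolygon:
    """Reviewer delineation on one native frame, in (u, v) pixel coordinates."""

    frame_index: int
    vertices: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("annotation polygon needs >= 3 (u, v) vertices")
        object.__setattr__(self, "vertices", v)


@dataclass
class AnnotationPointCloud:
    points: np.ndarray  # (n, 3) world mm
    provenance: Provenance

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RegionOfInterest:
    slide_id: str
    polygon: np.ndarray  # (n, 2) closed polygon, mm
    provenance: Provenance
    mask: np.ndarray | None = None
    grid: Grid2D | None = None

    def rasterize(self, grid: Grid2D) -> np.ndarray:
        self.mask = polygon_mask(self.polygon, grid)
        self.grid = grid
        return self.mask


def polygon_to_pointcloud(
    annotation: AnnotationPolygon, frame: FanFrame, sample_spacing_mm: float = 1.0
) -> AnnotationPointCloud:
    """Sample the annotation interior on a mm grid and lift the samples to 3D.

    The polygon interior is sampled on an axis-aligned grid of the given
    spacing in frame-plane mm, then each sample is placed in world
    coordinates with the same geometry used for image reconstruction.
    """
    if sample_spacing_mm <= 0:
        raise ValueError("sample_spacing_mm must be positive")
    su, sv = frame.in_plane_spacing
    verts_mm = annotation.vertices * np.array([su, sv])
    poly = Polygon(verts_mm)
    if poly.area == 0:
        raise ValueError("annotation polygon has empty interior")

    lo = np.floor(verts_mm.min(axis=0) / sample_spacing_mm) * sample_spacing_mm
    hi = verts_mm.max(axis=0)
    du = np.arange(lo[0], hi[0] + sample_spacing_mm, sample_spacing_mm)
    dv = np.arange(lo[1], hi[1] + sample_spacing_mm, sample_spacing_mm)
    DU, DV = np.meshgrid(du, dv, indexing="ij")
    samples = np.column_stack([DU.ravel(), DV.ravel()])
    inside = Path(verts_mm).contains_points(samples)
    samples = samples[inside]

    nu, nv = frame.shape
    u = samples[:, 0] / su
    v = samples[:, 1] / sv
    ok = (u >= 0) & (u <= nu - 1) & (v >= 0) & (v <= nv - 1)
    if not ok.any():
        raise ValueError("annotation polygon lies entirely outside the frame")
    world = frame_pixel_to_world(frame, u[ok], v[ok])
    return AnnotationPointCloud(points=world, provenance=annotation.provenance)


def merge_pointclouds(clouds: list[AnnotationPointCloud]) -> AnnotationPointCloud:
    """Concatenate clouds sharing identical provenance."""
    if not clouds:
        raise ValueError("no clouds to merge")
    prov = clouds[0].provenance
    if any(c.provenance != prov for c in clouds):
        raise ValueError("refusing to merge clouds with mixed provenance")
    return AnnotationPointCloud(
        points=np.vstack([c.points for c in clouds]), provenance=prov
    )


# ---------------------------------------------------------------------------
# slice assignment and the full chain


@dataclass(frozen=True)
class SliceAssigner:
    """Assign an axial (x) coordinate to the WM slide whose matched MRI window contains it.

    Each slide's window is its matched MRI slice center ± 1.5 x the MRI slice
    spacing; points outside every window are dropped. Ties go to the nearer
    matched slice center (resolved automatically by nearest-center lookup).
    """

    slide_ids: tuple[str, ...]
    slide_centers_x_mm: np.ndarray
    mri_spacing_mm: float
    window_factor: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "slide_centers_x_mm",
            np.asarray(self.slide_centers_x_mm, dtype=float),
        )
        if len(self.slide_ids) != len(self.slide_centers_x_mm):
            raise ValueError("slide ids and centers must align")

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Return per-point slide index, or -1 for dropped points."""
        x = np.asarray(x, dtype=float)
        d = np.abs(x[:, None] - self.slide_centers_x_mm[None, :])
        nearest = d.argmin(axis=1)
        within = d[np.arange(len(x)), nearest] <= self.window_factor * self.mri_spacing_mm
        return np.where(within, nearest, -1)


@dataclass
class ChainResult:
    per_slide: dict[str, np.ndarray]  # slide_id -> (m, 2) points
    n_dropped: int
    provenance: Provenance


def transform_chain(
    cloud: AnnotationPointCloud,
    volume_transforms: list,
    assigner: SliceAssigner,
    slide_transforms: dict[str, object],
) -> ChainResult:
    """Apply the stored chain: 3D warp(s), slice assignment, per-slide 2D warp.

    Every input point either lands on exactly one slide or is dropped as
    outside all matched windows; the dropped count is reported so point
    conservation can be audited.
    """
    pts3 = apply_transform(volume_transforms, cloud.points) if volume_transforms else cloud.points
    idx = assigner.assign(pts3[:, 0])
    per_slide: dict[str, np.ndarray] = {}
    for k, slide_id in enumerate(assigner.slide_ids):
        sel = pts3[idx == k][:, 1:]
        if len(sel) == 0:
            continue
        if slide_id not in slide_transforms:
            raise KeyError(f"no 2D transform stored for assigned slide {slide_id!r}")
        per_slide[slide_id] = apply_transform(slide_transforms[slide_id], sel)
    n_dropped = int((idx == -1).sum())
    if n_dropped:
        logger.info(
            "%d/%d points fell outside all matched slide windows",
            n_dropped, len(cloud),
        )
    return ChainResult(per_slide=per_slide, n_dropped=n_dropped, provenance=cloud.provenance)


# ---------------------------------------------------------------------------
# clustering and ROI extraction


def dbscan_cluster(
    points: np.ndarray, eps_mm: float, min_pts: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Standard DBSCAN partition of a 2D point set into clusters plus noise.

    Border points are attached to the first core cluster reaching them in the
    deterministic scan order, so output depends only on the input ordering.
    """
    if eps_mm <= 0:
        raise ValueError("eps_mm must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    if len(pts) == 0:
        return [], np.empty((0, 2))
    labels = DBSCAN(eps=eps_mm, min_samples=min_pts).fit_predict(pts)
    clusters = [pts[labels == lab] for lab in range(labels.max() + 1)]
    return clusters, pts[labels == -1]


def clusters_to_rois(
    clusters: list[np.ndarray],
    slide_id: str,
    provenance: Provenance,
    hull: str = "convex",
    alpha_mm: float = 4.0,
) -> list[RegionOfInterest]:
    """Outline each cluster as a region of interest.

    Clusters with fewer than 3 non-collinear points cannot form an area and
    are discarded (logged). The outline is the convex hull by default; a
    crude concave alternative (hull="buffer", a close/open morphological
    buffer of radius ``alpha_mm``) is available for concave lesions.
    """
    rois = []
    for i, cluster in enumerate(clusters):
        cluster = np.asarray(cluster, dtype=float)
        geom = MultiPoint([tuple(p) for p in cluster])
        if hull == "buffer":
            shape = geom.buffer(alpha_mm).buffer(-alpha_mm * 0.5)
        else:
            shape = geom.convex_hull
        if shape.geom_type != "Polygon" or shape.area == 0:
            logger.info(
                "cluster %d on slide %s is degenerate (%d points); discarded",
                i, slide_id, len(cluster),
            )
            continue
        rois.append(
            RegionOfInterest(
                slide_id=slide_id,
                polygon=np.asarray(shape.exterior.coords)[:-1],
                provenance=provenance,
            )
        )
    return rois
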