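"""Synthetic digital-prostate phantom and simulated acquisitions.

The phantom is an analytic scene — an ellipsoidal gland with capsule, a
coaxial transition zone, a curved urethra, ellipsoidal lesions with ISUP
grade groups, and point fiducials — voxelized onto a regular grid. Three
acquisitions are simulated from it with known ground-truth correspondences:

* a rotational fan sweep of 2D frames (the micro-ultrasound geometry),
* an axial MRI volume under a smooth global deformation,
* thick whole-mount (WM) sections with per-slide in-plane deformation and
  uniform shrinkage.

Because every simulated output is generated from the same analytic scene,
registration and metric code can be validated against exact ground truth
without patient data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .capsule_registration import CapsuleContour
from .fan_reconstruction import FanFrame, FanSweep, ImageVolume, frame_pixel_to_world
from .landmark_registration import Landmark, fit_tps

logger = logging.getLogger(__name__)

BACKGROUND_INTENSITY = 0.05
URETHRA_RADIUS_MM = 1.0
TRANSITION_ZONE_SCALE = 0.55


@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal lesion; center is an offset from the gland center in mm."""

    center_offset: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    grade_group: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semiaxes):
            raise ValueError("lesion semiaxes must be positive")
        if not 1 <= self.grade_group <= 5:
            raise ValueError("grade_group must be in 1..5")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic prostate; seed determines everything."""

    gland_semiaxes: tuple[float, float, float] = (13.5, 22.0, 18.0)
    urethra_waypoints: tuple | None = None  # offsets from gland center; None = default curve
    lesion_specs: tuple[LesionSpec, ...] = (
        LesionSpec((0.0, 8.0, 4.0), (6.0, 7.0, 5.5), 3),
        LesionSpec((-4.0, -9.0, -5.0), (4.0, 4.5, 4.0), 2),
    )
    fiducial_count: int = 5
    voxel_spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.gland_semiaxes):
            raise ValueError("gland semiaxes must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.fiducial_count < 0:
            raise ValueError("fiducial_count must be nonnegative")
        object.__setattr__(self, "lesion_specs", tuple(self.lesion_specs))

    @property
    def gland_center(self) -> np.ndarray:
        """Gland center placed so the whole gland sits at x > 0, z > 0 (above the probe axis)."""
        sx, _, sz = self.gland_semiaxes
        return np.array([sx + 5.0, 0.0, sz + 6.0])


@dataclass
class LesionMask:
    lesion_id: str
    mask: ImageVolume
    grade_group: int
    center: np.ndarray
    semiaxes: np.ndarray


@dataclass
class PhantomScene:
    """Voxelized phantom plus the analytic parameters it was generated from."""

    spec: PhantomSpec
    intensity_volume: ImageVolume
    capsule_mask: ImageVolume
    transition_zone_mask: ImageVolume
    lesion_masks: list[LesionMask]
    urethra_polyline: np.ndarray  # (n, 3) mm
    fiducials: dict[str, np.ndarray]

    @property
    def gland_center(self) -> np.ndarray:
        return self.spec.gland_center

    @property
    def gland_semiaxes(self) -> np.ndarray:
        return np.asarray(self.spec.gland_semiaxes, dtype=float)

    @property
    def axial_extent_mm(self) -> float:
        return 2.0 * self.gland_semiaxes[0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.intensity_volume.voxels.tobytes())
        h.update(self.capsule_mask.voxels.tobytes())
        h.update(self.transition_zone_mask.voxels.tobytes())
        for lm in self.lesion_masks:
            h.update(lm.mask.voxels.tobytes())
        for name in sorted(self.fiducials):
            h.update(self.fiducials[name].tobytes())
        return h.hexdigest()

    def capsule_cross_section(self, x: float, n_points: int = 180) -> np.ndarray | None:
        return _ellipsoid_cross_section(
            self.gland_center, self.gland_semiaxes, x, n_points
        )

    def transition_zone_cross_section(
        self, x: float, n_points: int = 180
    ) -> np.ndarray | None:
        return _ellipsoid_cross_section(
            self.gland_center, self.gland_semiaxes * TRANSITION_ZONE_SCALE, x, n_points
        )


def _ellipsoid_cross_section(
    center: np.ndarray, semiaxes: np.ndarray, x: float, n_points: int
) -> np.ndarray | None:
    """(y, z) ellipse polygon of an axis-aligned ellipsoid cut at plane x, or None."""
    t = (x - center[0]) / semiaxes[0]
    if abs(t) >= 1.0:
        return None
    shrink = np.sqrt(1.0 - t * t)
    ang = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack(
        [
            center[1] + semiaxes[1] * shrink * np.cos(ang),
            center[2] + semiaxes[2] * shrink * np.sin(ang),
        ]
    )


def _fibonacci_sphere(n: int = 256) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    zc = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - zc**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), zc])


def _default_urethra_waypoints(semiaxes: np.ndarray) -> np.ndarray:
    sx, _, sz = semiaxes
    return np.array(
        [
            [-0.85 * sx, 0.0, -0.10 * sz],
            [0.0, 0.0, -0.22 * sz],
            [0.85 * sx, 0.0, -0.10 * sz],
        ]
    )


def generate_scene(spec: PhantomSpec) -> PhantomScene:
    """Voxelize the analytic phantom described by ``spec``.

    Deterministic: repeated calls with the same spec (including seed) produce
    bit-identical arrays.
    """
    center = spec.gland_center
    semiaxes = np.asarray(spec.gland_semiaxes, dtype=float)

    # validate lesion containment against the analytic gland
    sphere = _fibonacci_sphere()
    for idx, lesion in enumerate(spec.lesion_specs):
        surface = (
            center
            + np.asarray(lesion.center_offset)
            + sphere * np.asarray(lesion.semiaxes)
        )
        if np.any((((surface - center) / semiaxes) ** 2).sum(axis=1) > 1.0):
            raise ValueError(f"lesion {idx} extends outside the gland ellipsoid")

    margin = 4.0
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    lo = center - semiaxes - margin
    hi = center + semiaxes + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing[k])) + 1 for k in range(3))
    xs, ys, zs = (lo[k] + np.arange(shape[k]) * spacing[k] for k in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    def inside_ellipsoid(c, s):
        return (((pts - c) / s) ** 2).sum(axis=-1) <= 1.0

    capsule = inside_ellipsoid(center, semiaxes)
    tz = inside_ellipsoid(center, semiaxes * TRANSITION_ZONE_SCALE)

    # urethra: smooth curve through waypoints, voxelized as a thin tube
    wp = (
        np.asarray(spec.urethra_waypoints, dtype=float)
        if spec.urethra_waypoints is not None
        else _default_urethra_waypoints(semiaxes)
    ) + center
    t = np.linspace(0.0, 1.0, len(wp))
    spline = make_interp_spline(t, wp, k=min(3, len(wp) - 1))
    polyline = spline(np.linspace(0.0, 1.0, 200))
    tube_dist, _ = cKDTree(polyline).query(pts[capsule])
    urethra_flat = tube_dist <= URETHRA_RADIUS_MM

    intensity = np.full(shape, BACKGROUND_INTENSITY)
    gland_tex = 0.5 + 0.15 * np.cos(X / 6.0) * np.cos(Y / 7.0) * np.cos(Z / 8.0)
    intensity[capsule] = gland_tex[capsule]
    intensity[tz] = 0.35 + 0.1 * np.cos(X / 5.0)[tz]

    lesion_masks = []
    for idx, lesion in enumerate(spec.lesion_specs):
        lcenter = center + np.asarray(lesion.center_offset)
        lmask = inside_ellipsoid(lcenter, np.asarray(lesion.semiaxes))
        intensity[lmask] = 0.85
        lesion_masks.append(
            LesionMask(
                lesion_id=f"lesion_{idx}",
                mask=ImageVolume(lmask, tuple(spacing), tuple(lo)),
                grade_group=lesion.grade_group,
                center=lcenter,
                semiaxes=np.asarray(lesion.semiaxes, dtype=float),
            )
        )

    ure_vals = intensity[capsule]
    ure_vals[urethra_flat] = 0.15
    intensity[capsule] = ure_vals

    rng = np.random.default_rng(spec.seed)
    fiducials: dict[str, np.ndarray] = {}
    k = 0
    while len(fiducials) < spec.fiducial_count:
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p**2).sum() <= 1.0:
            fiducials[f"fiducial_{k}"] = center + 0.6 * semiaxes * p
            k += 1

    mk = lambda arr: ImageVolume(arr, tuple(spacing), tuple(lo))
    return PhantomScene(
        spec=spec,
        intensity_volume=ImageVolume(
            intensity, tuple(spacing), tuple(lo), background=BACKGROUND_INTENSITY
        ),
        capsule_mask=mk(capsule),
        transition_zone_mask=mk(tz),
        lesion_masks=lesion_masks,
        urethra_polyline=polyline,
        fiducials=fiducials,
    )


def sample_scene_intensity(scene: PhantomScene, points: np.ndarray) -> np.ndarray:
    """Trilinear samples of the scene intensity at world mm points."""
    vol = scene.intensity_volume
    idx = vol.world_to_index(points)
    return map_coordinates(
        vol.voxels, idx.T, order=1, mode="constant", cval=vol.background
    )


def scene_control_landmarks(
    scene: PhantomScene, n_capsule_per_ring: int = 8
) -> list[Landmark]:
    """Urethra apex/mid/base points plus capsule rings in 3 axial frames.

    Mirrors the clinical control-point selection: 3 points along the urethra
    and evenly spaced capsule points at apex, mid-gland and base.
    """
    landmarks = []
    n = len(scene.urethra_polyline)
    for label, frac in (("urethra_apex", 0.1), ("urethra_mid", 0.5), ("urethra_base", 0.9)):
        landmarks.append(
            Landmark(label, scene.urethra_polyline[int(frac * (n - 1))], "control")
        )
    cx = scene.gland_center[0]
    sx = scene.gland_semiaxes[0]
    for ring, xoff in (("apex", -0.6 * sx), ("mid", 0.0), ("base", 0.6 * sx)):
        ellipse = scene.capsule_cross_section(cx + xoff, n_points=n_capsule_per_ring)
        for i, (y, z) in enumerate(ellipse):
            landmarks.append(
                Landmark(f"capsule_{ring}_{i}", np.array([cx + xoff, y, z]), "control")
            )
    return landmarks


# ---------------------------------------------------------------------------
# deformation fields


class _IdentityTransform:
    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float))


class _TranslationTransform:
    def __init__(self, shift: np.ndarray):
        self.shift = np.asarray(shift, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float)) + self.shift


@dataclass
class DeformationField:
    """Invertible smooth deformation used to corrupt simulated acquisitions."""

    kind: str  # affine | tps | composite
    transform: object
    magnitude_mm: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.transform.apply(points)

    def inverse(self, points: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
        """Numerical inverse by fixed-point iteration (valid for small warps)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = p.copy()
        for _ in range(max_iter):
            residual = self.apply(q) - p
            q = q - residual
            if np.abs(residual).max() < tol:
                return q
        raise ValueError("deformation could not be inverted (fixed point diverged)")

    def check_invertible(self, probe_points: np.ndarray, tol_mm: float = 0.01) -> None:
        back = self.inverse(self.apply(probe_points))
        err = np.linalg.norm(back - np.atleast_2d(probe_points), axis=1).max()
        if err > tol_mm:
            raise ValueError(f"deformation not invertible to {tol_mm} mm (err {err:.3g})")

    @classmethod
    def identity(cls) -> "DeformationField":
        return cls(kind="affine", transform=_IdentityTransform(), magnitude_mm=0.0)

    @classmethod
    def translation(cls, shift) -> "DeformationField":
        shift = np.asarray(shift, dtype=float)
        return cls(
            kind="affine",
            transform=_TranslationTransform(shift),
            magnitude_mm=float(np.linalg.norm(shift)),
        )


def random_tps_deformation(
    bounds_lo,
    bounds_hi,
    magnitude_mm: float,
    seed: int,
    in_plane_only: bool = False,
    n_grid: int = 3,
) -> DeformationField:
    """Random smooth TPS deformation with exact peak displacement over the bounds.

    Control displacements are drawn randomly, then rescaled so that the
    maximum displacement over a dense probe grid equals ``magnitude_mm``
    (TPS warps are linear in their targets, so rescaling is exact). With
    ``in_plane_only`` the first (axial) coordinate is left untouched, keeping
    slice correspondences exact.
    """
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    dim = len(lo)
    rng = np.random.default_rng(seed)
    axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(dim)]
    ctrl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, dim)
    disp = rng.normal(size=ctrl.shape)
    if in_plane_only:
        disp[:, 0] = 0.0
    if magnitude_mm == 0:
        return DeformationField.identity()

    probe_axes = [np.linspace(lo[k], hi[k], 9) for k in range(dim)]
    probe = np.stack(np.meshgrid(*probe_axes, indexing="ij"), axis=-1).reshape(-1, dim)

    tps = fit_tps(ctrl, ctrl + disp, dimension=dim)
    peak = np.linalg.norm(tps.apply(probe) - probe, axis=1).max()
    disp *= magnitude_mm / peak
    tps = fit_tps(ctrl, ctrl + disp, dimension=dim)
    return DeformationField(kind="tps", transform=tps, magnitude_mm=float(magnitude_mm))


# ---------------------------------------------------------------------------
# simulated acquisitions


def simulate_fan_sweep(
    scene: PhantomScene,
    n_frames: int = 300,
    angle_range: tuple[float, float] = (-70.0, 70.0),
    offset_mm: float = 2.0,
    in_plane_spacing: tuple[float, float] = (0.5, 0.5),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FanSweep:
    """Simulate a rotational fan sweep by sampling the scene on each frame plane.

    Frame ``i`` carries an angle linearly spaced over ``angle_range``; pixels
    are trilinear samples of the scene intensity at the world position given
    by the reconstruction geometry, so reconstruction is exercised as an
    exact round trip.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames > 1 and angle_range[1] <= angle_range[0]:
        raise ValueError("angle range must be strictly increasing")
    if offset_mm < 0:
        raise ValueError("offset_mm must be nonnegative")
    su, sv = in_plane_spacing

    vol = scene.intensity_volume
    x_hi = vol.origin[0] + (vol.shape[0] - 1) * vol.spacing[0]
    corners_yz = [
        (vol.origin[1] + iy * (vol.shape[1] - 1) * vol.spacing[1],
         vol.origin[2] + iz * (vol.shape[2] - 1) * vol.spacing[2])
        for iy in (0, 1) for iz in (0, 1)
    ]
    r_max = max(np.hypot(y, z) for y, z in corners_yz)
    nu = int(np.ceil((r_max - offset_mm) / su)) + 1
    nv = int(np.ceil(x_hi / sv)) + 1

    angles = np.linspace(angle_range[0], angle_range[1], n_frames)
    rng = np.random.default_rng(seed)
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    frames = []
    for theta in angles:
        probe = FanFrame(
            pixels=np.zeros((nu, nv)),
            angle_deg=float(theta),
            in_plane_spacing=(su, sv),
            offset_mm=offset_mm,
        )
        world = frame_pixel_to_world(probe, uu, vv).reshape(-1, 3)
        pixels = sample_scene_intensity(scene, world).reshape(nu, nv)
        if noise_sd > 0:
            pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
        frames.append(
            FanFrame(pixels, float(theta), (su, sv), offset_mm)
        )
    return FanSweep(tuple(frames), monotone=n_frames > 1)


def simulate_mri_volume(
    scene: PhantomScene,
    deformation: DeformationField,
    slice_spacing_mm: float = 1.5,
    in_plane_spacing_mm: float | None = None,
) -> tuple[ImageVolume, dict[str, np.ndarray]]:
    """Axial resampling of the deformed scene plus ground-truth fiducials.

    The MRI voxel at world point p holds the scene intensity at the
    deformation's inverse of p; fiducial ground truth is the forward
    deformation of the scene fiducials (for TRE evaluation).
    """
    if slice_spacing_mm <= 0:
        raise ValueError("slice_spacing_mm must be positive")
    vol = scene.intensity_volume
    inplane = in_plane_spacing_mm or vol.spacing[1]

    probe = (
        np.array(list(scene.fiducials.values()))
        if scene.fiducials
        else scene.gland_center[None, :]
    )
    deformation.check_invertible(probe)

    spacing = (slice_spacing_mm, inplane, inplane)
    extent = [
        (vol.origin[k], vol.origin[k] + (vol.shape[k] - 1) * vol.spacing[k])
        for k in range(3)
    ]
    shape = tuple(
        int(np.floor((extent[k][1] - extent[k][0]) / spacing[k])) + 1 for k in range(3)
    )
    axes = [extent[k][0] + np.arange(shape[k]) * spacing[k] for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if deformation.magnitude_mm == 0:
        source = grid
    else:
        source = deformation.inverse(grid)
    voxels = sample_scene_intensity(scene, source).reshape(shape)
    mri = ImageVolume(
        voxels,
        spacing,
        tuple(extent[k][0] for k in range(3)),
        background=vol.background,
        metadata={"slice_spacing_mm": slice_spacing_mm},
    )
    fid_true = {
        name: deformation.apply(pos)[0] for name, pos in scene.fiducials.items()
    }
    return mri, fid_true


@dataclass
class WMLesionSection:
    lesion_id: str
    grade_group: int
    vertices: np.ndarray  # (n, 2) slide-coordinate polygon


@dataclass
class WMSlide:
    slide_id: str
    center_x_mm: float
    capsule: CapsuleContour
    transition_zone: CapsuleContour
    lesions: list[WMLesionSection]
    fiducials: dict[str, np.ndarray]  # ground-truth 2D positions in slide coords
    true_transform: object  # maps undeformed scene (y, z) -> slide coords


class _ShrinkThenWarp:
    """Uniform shrink about a center followed by an optional 2D deformation."""

    def __init__(self, center2d: np.ndarray, shrink: float, deformation: DeformationField):
        self.center = np.asarray(center2d, dtype=float)
        self.shrink = float(shrink)
        self.deformation = deformation

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        shrunk = self.center + self.shrink * (p - self.center)
        return self.deformation.apply(shrunk)


@dataclass
class WMSlideSet:
    slides: list[WMSlide]
    section_thickness_mm: float
    shrink_factor: float

    def __len__(self) -> int:
        return len(self.slides)


def simulate_wm_slides(
    scene: PhantomScene,
    deformation_per_slide: list[DeformationField] | None = None,
    section_thickness_mm: float = 4.5,
    shrink_factor: float = 0.95,
    n_contour_points: int = 180,
) -> WMSlideSet:
    """Cut the (shrunken, per-slide deformed) gland into thick axial sections.

    Slide count is ceil(gland axial extent / thickness); each slide carries
    capsule, transition-zone and lesion contours at the section center plane
    plus ground-truth fiducial positions for slab fiducials. Sections that
    miss the gland are omitted and logged.
    """
    if not 0 < shrink_factor <= 1:
        raise ValueError("shrink_factor must be in (0, 1]")
    if section_thickness_mm <= 0:
        raise ValueError("section thickness must be positive")
    center = scene.gland_center
    sx = scene.gland_semiaxes[0]
    x0 = center[0] - sx
    n_slides = int(np.ceil(scene.axial_extent_mm / section_thickness_mm))
    if deformation_per_slide is None:
        deformation_per_slide = [DeformationField.identity()] * n_slides
    if len(deformation_per_slide) != n_slides:
        raise ValueError(
            f"need {n_slides} per-slide deformations, got {len(deformation_per_slide)}"
        )

    slides = []
    for k in range(n_slides):
        cx = x0 + (k + 0.5) * section_thickness_mm
        capsule_xy = scene.capsule_cross_section(cx, n_contour_points)
        if capsule_xy is None:
            logger.warning("section %d at x=%.2f mm misses the gland; omitted", k, cx)
            continue
        slide_id = f"wm_{k:02d}"
        warp = _ShrinkThenWarp(center[1:], shrink_factor, deformation_per_slide[k])

        tz_xy = scene.transition_zone_cross_section(cx, n_contour_points)
        lesions = []
        for lm in scene.lesion_masks:
            sec = _ellipsoid_cross_section(lm.center, lm.semiaxes, cx, n_contour_points)
            if sec is not None:
                lesions.append(
                    WMLesionSection(lm.lesion_id, lm.grade_group, warp.apply(sec))
                )
        slab_lo, slab_hi = cx - section_thickness_mm / 2, cx + section_thickness_mm / 2
        fids = {
            name: warp.apply(pos[1:])[0]
            for name, pos in scene.fiducials.items()
            if slab_lo <= pos[0] < slab_hi
        }
        slides.append(
            WMSlide(
                slide_id=slide_id,
                center_x_mm=cx,
                capsule=CapsuleContour(slide_id, "capsule", warp.apply(capsule_xy)),
                transition_zone=CapsuleContour(
                    slide_id, "transition_zone", warp.apply(tz_xy)
                )
                if tz_xy is not None
                else None,
                lesions=lesions,
                fiducials=fids,
                true_transform=warp,
            )
        )
    return WMSlideSet(
        slides=slides,
        section_thickness_mm=section_thickness_mm,
        shrink_factor=shrink_factor,
    )
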