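"""End-to-end synthetic pipeline: simulate -> reconstruct -> register -> evaluate.

Runs the full three-step co-registration chain on a synthetic phantom with
known ground truth, then maps a simulated lesion-tracing annotation through
the fitted (not ground-truth) transforms and scores it against the true WM
lesion outlines. Every stage parameter lives in :class:`PipelineConfig` and
is echoed, with a content hash, into the machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage import measure

from . import __version__
from .annotation_pipeline import (
    AnnotationPolygon,
    Provenance,
    SliceAssigner,
    clusters_to_rois,
    dbscan_cluster,
    merge_pointclouds,
    polygon_to_pointcloud,
    transform_chain,
)
from .capsule_registration import (
    SlideCorrespondence,
    register_slice,
    transition_zone_dice,
    validate_slide_correspondence,
)
from .concordance_metrics import (
    LesionCrossSection,
    aggregate,
    detect_hits,
    overlap_percent,
)
from .fan_reconstruction import frame_pixel_to_world, reconstruct_volume
from .landmark_registration import (
    combine_quadrature,
    compute_tre,
    exclude_tre_outliers,
    fit_tps,
    initialize_alignment,
    landmark_array,
)
from .phantom import (
    CapsuleContour,
    DeformationField,
    PhantomSpec,
    generate_scene,
    random_tps_deformation,
    scene_control_landmarks,
    simulate_fan_sweep,
    simulate_mri_volume,
    simulate_wm_slides,
)
from .raster import grid_for_polygons, polygon_mask

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    # fan sweep
    n_frames: int = 150
    angle_range: tuple[float, float] = (-70.0, 70.0)
    in_plane_spacing: tuple[float, float] = (0.6, 0.6)
    noise_sd: float = 0.01
    plane_spacing_mm: float = 1.0
    bin_halfwidth_mm: float = 0.5
    # MRI
    mri_slice_spacing_mm: float = 1.5
    mri_deformation_mm: float = 4.0
    # WM
    wm_thickness_mm: float = 4.5
    wm_deformation_mm: float = 2.0
    shrink_factor: float = 0.95
    # registration
    tps_regularization: float = 0.0
    capsule_n_points: int = 64
    tps_control_stride: int = 4
    # annotation mapping
    annotation_frame_stride: int = 2
    annotation_sample_spacing_mm: float = 0.5
    dbscan_eps_mm: float = 2.0
    dbscan_min_pts: int = 5
    # raster
    pixel_mm: float = 0.2

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def trace_lesion_annotations(
    scene,
    sweep,
    lesion_index: int = 0,
    frame_stride: int = 3,
    provenance: Provenance | None = None,
) -> list[AnnotationPolygon]:
    """Simulate a reviewer exactly tracing one lesion on native sweep frames.

    For every ``frame_stride``-th frame whose plane cuts the lesion, the
    analytic lesion cross-section is outlined in frame pixel coordinates.
    """
    lesion = scene.lesion_masks[lesion_index]
    prov = provenance or Provenance("sim_reviewer", "microUS", "phantom")
    annotations = []
    nu, nv = sweep.frames[0].shape
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    for frame_index in range(0, len(sweep.frames), frame_stride):
        frame = sweep.frames[frame_index]
        world = frame_pixel_to_world(frame, uu, vv)
        inside = (((world - lesion.center) / lesion.semiaxes) ** 2).sum(axis=-1) <= 1.0
        if inside.sum() < 12:
            continue
        contours = measure.find_contours(inside.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        step = max(1, len(contour) // 40)
        verts = contour[::step]
        if len(verts) < 3:
            continue
        annotations.append(
            AnnotationPolygon(frame_index=frame_index, vertices=verts, provenance=prov)
        )
    if not annotations:
        raise ValueError("lesion is not visible on any selected frame")
    return annotations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a synthetic subject and return the report dict."""
    rpt: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
    }

    # --- stage 1: phantom + fan sweep + reconstruction -------------------
    scene = generate_scene(PhantomSpec(seed=config.seed))
    sweep = simulate_fan_sweep(
        scene,
        n_frames=config.n_frames,
        angle_range=config.angle_range,
        in_plane_spacing=config.in_plane_spacing,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    recon = reconstruct_volume(
        sweep,
        plane_spacing_mm=config.plane_spacing_mm,
        bin_halfwidth_mm=config.bin_halfwidth_mm,
    )
    rpt["reconstruction"] = {
        "n_frames": len(sweep),
        "volume_shape": list(recon.shape),
        "plane_spacing_mm": config.plane_spacing_mm,
    }

    # --- stage 2: 3D landmark registration (US -> MRI) -------------------
    vol = scene.intensity_volume
    lo = np.asarray(vol.origin)
    hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    mri_deform = random_tps_deformation(
        lo, hi, config.mri_deformation_mm, seed=config.seed + 1, in_plane_only=True
    )
    mri, fid_true = simulate_mri_volume(
        scene, mri_deform, slice_spacing_mm=config.mri_slice_spacing_mm
    )

    controls = scene_control_landmarks(scene)
    src = landmark_array(controls)
    tgt = mri_deform.apply(src)
    capsule_src = src[3:]  # capsule ring points only, for the rigid init
    rigid = initialize_alignment(capsule_src, mri_deform.apply(capsule_src))
    tps3d = fit_tps(
        rigid.apply(src), tgt, dimension=3, regularization=config.tps_regularization
    )
    us_to_mri = [rigid, tps3d]

    fid_names = sorted(scene.fiducials)
    fid_src = np.array([scene.fiducials[n] for n in fid_names])
    fid_tgt = np.array([fid_true[n] for n in fid_names])
    tre_pre = compute_tre(fid_src, fid_tgt)
    tre1 = compute_tre(fid_src, fid_tgt, transform=us_to_mri)
    rpt["us_to_mri"] = {
        "pre_registration_tre_mm": tre_pre.mean_mm,
        "tre": tre1.to_dict(),
    }

    # --- stage 3: 2D capsule registration (MRI -> WM) --------------------
    n_slides = int(np.ceil(scene.axial_extent_mm / config.wm_thickness_mm))
    gl_lo = scene.gland_center[1:] - scene.gland_semiaxes[1:]
    gl_hi = scene.gland_center[1:] + scene.gland_semiaxes[1:]
    wm_defs = [
        random_tps_deformation(
            gl_lo, gl_hi, config.wm_deformation_mm, seed=config.seed + 100 + k
        )
        for k in range(n_slides)
    ]
    wm = simulate_wm_slides(
        scene,
        wm_defs,
        section_thickness_mm=config.wm_thickness_mm,
        shrink_factor=config.shrink_factor,
    )

    corr = SlideCorrespondence(
        entries=[
            (
                s.slide_id,
                int(round((s.center_x_mm - mri.origin[0]) / config.mri_slice_spacing_mm)),
            )
            for s in wm.slides
        ],
        mri_slice_spacing_mm=config.mri_slice_spacing_mm,
        wm_thickness_mm=config.wm_thickness_mm,
    )
    corr_report = validate_slide_correspondence(corr)
    if not corr_report.ok:
        raise RuntimeError(
            f"capsule_registration stage: slide correspondence invalid: "
            f"{corr_report.violations}"
        )

    def mri_contour(xsec_fn, x):
        """Scene cross-section as it appears on the deformed MRI (in-plane warp)."""
        sec = xsec_fn(x)
        if sec is None:
            return None
        pts3 = np.column_stack([np.full(len(sec), x), sec])
        return mri_deform.apply(pts3)[:, 1:]

    slide_transforms = {}
    step2_distances = []
    tz_dices = []
    for slide in wm.slides:
        moving = mri_contour(scene.capsule_cross_section, slide.center_x_mm)
        xf = register_slice(
            CapsuleContour(slide.slide_id, "capsule", moving),
            slide.capsule,
            n_points=config.capsule_n_points,
            tps_control_stride=config.tps_control_stride,
            regularization=config.tps_regularization,
        )
        slide_transforms[slide.slide_id] = xf
        if slide.transition_zone is not None:
            mov_tz = mri_contour(
                scene.transition_zone_cross_section, slide.center_x_mm
            )
            if mov_tz is not None:
                tz_dices.append(
                    transition_zone_dice(
                        slide.transition_zone,
                        CapsuleContour(slide.slide_id, "transition_zone", mov_tz),
                        transform=xf,
                        pixel_mm=config.pixel_mm,
                    )
                )
        for name, true2d in slide.fiducials.items():
            mri2d = mri_deform.apply(scene.fiducials[name])[0][1:]
            moved = xf.apply(mri2d)[0]
            step2_distances.append(float(np.linalg.norm(moved - true2d)))

    kept, excluded = exclude_tre_outliers(np.array(step2_distances))
    tre2_mean = float(np.mean(kept))
    tre2_se = (
        float(np.std(kept, ddof=1) / np.sqrt(len(kept))) if len(kept) > 1 else 0.0
    )
    combined_mean, combined_se = combine_quadrature(
        [tre1.mean_mm, tre2_mean], [tre1.se_mm, tre2_se]
    )
    rpt["mri_to_wm"] = {
        "n_slides": len(wm.slides),
        "tre_mean_mm": tre2_mean,
        "tre_se_mm": tre2_se,
        "n_landmarks": len(step2_distances),
        "n_excluded": len(excluded),
        "transition_zone_dice_mean": float(np.mean(tz_dices)) if tz_dices else None,
    }
    rpt["combined_tre_mm"] = {"mean": combined_mean, "se": combined_se}

    # --- stage 4: annotation mapping -------------------------------------
    annotations = trace_lesion_annotations(
        scene, sweep, lesion_index=0, frame_stride=config.annotation_frame_stride
    )
    clouds = [
        polygon_to_pointcloud(
            ann, sweep.frames[ann.frame_index], config.annotation_sample_spacing_mm
        )
        for ann in annotations
    ]
    cloud = merge_pointclouds(clouds)
    assigner = SliceAssigner(
        slide_ids=tuple(s.slide_id for s in wm.slides),
        slide_centers_x_mm=np.array([s.center_x_mm for s in wm.slides]),
        mri_spacing_mm=config.mri_slice_spacing_mm,
    )
    chained = transform_chain(cloud, us_to_mri, assigner, slide_transforms)

    rois = []
    for slide_id, pts in chained.per_slide.items():
        clusters, _noise = dbscan_cluster(
            pts, eps_mm=config.dbscan_eps_mm, min_pts=config.dbscan_min_pts
        )
        rois.extend(clusters_to_rois(clusters, slide_id, cloud.provenance))
    rpt["annotation"] = {
        "n_points": int(len(cloud)),
        "n_dropped": chained.n_dropped,
        "n_rois": len(rois),
    }

    # --- stage 5: evaluation ---------------------------------------------
    # index lesion: highest grade group, then largest total contour area
    from shapely.geometry import Polygon as ShPolygon

    lesion_area: dict[str, float] = {}
    lesion_gg: dict[str, int] = {}
    for slide in wm.slides:
        for sec in slide.lesions:
            lesion_area[sec.lesion_id] = lesion_area.get(sec.lesion_id, 0.0) + ShPolygon(
                sec.vertices
            ).area
            lesion_gg[sec.lesion_id] = sec.grade_group
    significant = {l for l, g in lesion_gg.items() if g >= 2}
    index_id = max(significant, key=lambda l: (lesion_gg[l], lesion_area[l]))

    cross_sections: list[LesionCrossSection] = []
    roi_masks = []
    traced_overlaps: list[tuple[float, float]] = []  # (area, overlap%)
    for slide in wm.slides:
        slide_rois = [r for r in rois if r.slide_id == slide.slide_id]
        polys = [sec.vertices for sec in slide.lesions] + [
            r.polygon for r in slide_rois
        ]
        if not polys:
            continue
        grid = grid_for_polygons(
            polys + [slide.capsule.vertices], pixel_mm=config.pixel_mm
        )
        for r in slide_rois:
            r.rasterize(grid)
            roi_masks.append(r)
        for sec in slide.lesions:
            xsec = LesionCrossSection(
                slide_id=slide.slide_id,
                lesion_id=sec.lesion_id,
                mask=polygon_mask(sec.vertices, grid),
                pixel_area_mm2=grid.pixel_area_mm2,
                grade_group=sec.grade_group,
                is_index=sec.lesion_id == index_id,
            )
            cross_sections.append(xsec)
            if sec.lesion_id == "lesion_0" and slide_rois:
                union = np.logical_or.reduce([r.mask for r in slide_rois])
                traced_overlaps.append(
                    (xsec.area_mm2, overlap_percent(xsec, union))
                )

    patient = detect_hits(
        cross_sections, roi_masks, "patient",
        subject_id="phantom", reviewer_id="sim_reviewer",
    )
    per_section = detect_hits(
        cross_sections, roi_masks, "cross_section",
        subject_id="phantom", reviewer_id="sim_reviewer",
    )
    metrics = aggregate([patient, per_section], by="modality")

    areas = np.array([a for a, _ in traced_overlaps])
    overlaps = np.array([o for _, o in traced_overlaps])
    traced_overlap = (
        float((areas * overlaps).sum() / areas.sum()) if len(areas) else 0.0
    )
    rpt["evaluation"] = {
        "index_lesion": index_id,
        "patient_level_hit": bool(patient.hits),
        "cross_sections_hit": per_section.hits,
        "cross_sections_total": per_section.opportunities,
        "traced_lesion_overlap_percent": traced_overlap,
        "metrics": metrics.to_dict(),
    }
    return rpt


def report_json(report: dict) -> str:
    """Deterministic machine-readable serialization of a run report."""
    return json.dumps(report, sort_keys=True, indent=2)
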