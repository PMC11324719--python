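# prostacoreg

Co-registration of para-sagittal micro-ultrasound fan sweeps, axial MRI and
whole-mount (WM) pathology slides into a common coordinate frame, plus the
evaluation statistics needed to compare imaging annotations against
ground-truth lesion outlines at patient, cross-section and pixel granularity.

Because no patient data ships with the package, a synthetic digital-prostate
phantom generates every input with known ground truth, so the full chain is
testable end to end.

## Pipeline

1. **Fan-sweep reconstruction** (`fan_reconstruction`) — frames acquired at
   varying rotation angles about the probe axis (with a 2 mm
   transducer-to-first-row offset) are placed in 3D, binned onto parallel
   planes at 1 mm spacing (mean per voxel bin, samples within ±0.5 mm of each
   plane), and holes are filled by per-plane gridded linear interpolation.
2. **3D landmark registration** (`landmark_registration`) — rigid
   initialization (centroid + principal axes, or a user-supplied transform)
   followed by a thin-plate-spline warp on urethra/capsule control points.
   Accuracy is reported as target registration error (TRE) on held-out
   evaluation landmarks, with single-pass mean + 2·SD outlier exclusion and
   quadrature combination of per-step errors.
3. **2D capsule registration** (`capsule_registration`) — each MRI slice is
   matched to a WM slide (correspondence validated, not computed), then
   registered by a least-squares similarity transform plus a TPS on
   corresponded capsule points (equal-arc-length resampling anchored at the
   posterior-most vertex). Transition-zone dice scores the result.
4. **Annotation mapping** (`annotation_pipeline`) — reviewer polygons drawn
   on native frames become 3D point-clouds, ride the stored transform chain
   into slide coordinates, and are clustered by DBSCAN into outlined ROIs.
5. **Concordance metrics** (`concordance_metrics`) — overlap, false-positive
   and dice percentages, per-slide sensitivity, index-lesion and
   cross-section hit rates (grade group ≥ 2 only), completely-false-ROI
   counts, area stratification and reviewer aggregation (mean ± SE and
   pooled fractions).

The `phantom` module simulates all three acquisitions (fan sweep, deformed
axial MRI, shrunken/deformed thick WM sections) from one analytic scene;
`pipeline`/`cli` orchestrate the whole flow.

Coordinate convention everywhere: `x` = probe long axis, `y` = left-right
plane-stacking axis, `z` = distance from the probe axis; lengths in mm.

## CLI

```sh
prostacoreg simulate --config phantom.yaml --out scene/ --seed 1
prostacoreg reconstruct --sweep sweep/ --angles angles.csv --spacing 1.0 --out recon/
prostacoreg register-us-mri --landmarks lm.json --out xform.json --report tre.json
prostacoreg register-mri-wm --mri-contours mri.json --wm-contours wm.json --corr corr.csv --out xforms/
prostacoreg map-annotations --annotations ann.json --chain xforms/ --out rois/
prostacoreg evaluate --rois rois/rois.json --lesions lesions.json --out report/
prostacoreg run-all --config pipeline.yaml --seed 1 --out report.json
```

`run-all` executes the complete synthetic pipeline (simulate → reconstruct →
register ×2 → map a lesion-tracing annotation → evaluate) and writes a single
deterministic JSON report containing per-step TREs, their quadrature
combination, transition-zone dice and the full metrics block. Volumes are
written as `.npy` with JSON geometry sidecars; landmarks, contours,
transforms and ROIs are JSON; angle/correspondence tables are CSV.

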