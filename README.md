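# fruitsize

Detector-agnostic fruit sizing from RGB-D images.

Harvesting robots and orchard phenotyping systems need the *metric
diameter* of each fruit — to set a gripper's opening angle, to grade by
size, to estimate yield. A neural detector localises the fruit, but a
bounding box alone gives neither a precise contour nor a physical size.
`fruitsize` implements the measurement half of that problem: given a
bounding box from **any** detector, an aligned depth raster, and the
camera intrinsics, it estimates the fruit's 3D position and its diameter
in millimetres.

## Method

Per detection, the pipeline runs:

1. **ROI preprocessing** — crop the (padded) box; grayscale; CLAHE
   contrast enhancement; Gaussian blur; Canny edge detection. The edge
   pixels form an unordered contour point cloud.
2. **Robust circle fit** — the silhouette is modelled as a circle
   `(x − a)² + (y − b)² = r²`. RANSAC draws 3-point samples, solves each
   exactly via the linear system in the algebraic circle parameters, and
   scores candidates by the inlier rule `|dᵢ − r| < ε` with
   `dᵢ = √((xᵢ − a)² + (yᵢ − b)²)`. After 1000 iterations the
   best-supported model drives a logistic *activation filter*

       Y = 1 / (1 + exp(α·(dᵢ − r)))

   that down-weights outliers; retained points are refit with an
   algebraic (Kåsa) least-squares circle.
3. **Back-projection** — the box centre `(px, py) = ((xmin+xmax)/2,
   (ymin+ymax)/2)`, with depth `z`, maps to camera coordinates
   `x = (px − ppx)/fx · z`, `y = (py − ppy)/fy · z`; positions can be
   averaged over a trailing 10-frame window to suppress depth noise.
4. **Metric diameter** — `D = 2·r_px·z·1000 / f̄` with `f̄ = (fx+fy)/2`.

The evaluation module provides the field-style accuracy statistics
(per-fruit deviation between reference and camera diameters, per-frame
dispersion about the reference, min–max error range) and detection
precision/recall `P = TP/(TP+FP)`, `R = TP/(TP+FN)`.

A synthetic scene generator renders fruit silhouettes with known
centre/radius/depth over background clutter — with partial occlusion,
Gaussian and salt-and-pepper noise, and brightness shifts — so the whole
chain is testable against exact ground truth without any field data.

## Worked example

```python
from fruitsize import SceneParams, generate_scene, detect_baseline, measure_image

params = SceneParams(diameter_mm=80.0, z_m=1.0, occlusion=0.1, noise_sigma=3.0, seed=7)
image, depth, truth = generate_scene(params)

detections = detect_baseline(image)          # or load_detections("detector_boxes.csv")
(record,) = measure_image(image, depth, params.intrinsics, detections)

print(f"status      : {record.status}")
print(f"pixel circle: a={record.circle.a:.2f}, b={record.circle.b:.2f}, r={record.circle.r:.2f} px")
print(f"3D centre   : x={record.position.x:.3f}, y={record.position.y:.3f}, z={record.position.z:.3f} m")
print(f"diameter    : {record.diameter_mm:.2f} mm   (ground truth {truth.diameter_mm:.2f} mm)")
print(f"inliers     : {record.fit.n_inliers} of {record.fit.inlier_mask.size} contour points")
```

prints

```
status      : ok
pixel circle: a=388.93, b=395.41, r=36.11 px
3D centre   : x=0.082, y=0.171, z=0.996 m
diameter    : 79.04 mm   (ground truth 80.00 mm)
inliers     : 203 of 260 contour points
```

An 80 mm fruit at ~1 m, 10% occluded by a branch and with sensor noise,
is measured to within about 1 mm; the RANSAC consensus kept 203 of the
260 Canny contour points (the rest belong to the occluder and background
clutter).

## Command line

```bash
fruitsize simulate --n 5 --seed 9 --outdir scenes/          # scene bundles + truth manifest
fruitsize measure  --image scenes/scene_000.png \
                   --depth scenes/scene_000_depth.png \
                   --intrinsics scenes/intrinsics.yaml \
                   --detect --out results.csv               # --detections file.csv to replay a detector
fruitsize evaluate --results series.csv --reference ref.csv --out report.csv
```

Exit codes: 0 success, 2 no detections, 3 nothing measurable, 4
input/config error, 5 evaluate join mismatch.

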