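# Methods

## Measurement model

A fruit's visible silhouette is modelled as a circle in the image plane,
`(x − a)² + (y − b)² = r²`. This is the central modelling assumption:
apples and similar pome fruit are nearly spherical, so their silhouette
under perspective is close to circular whenever the fruit is mostly
visible. The assumption fails for strongly elongated fruit, for
occlusions approaching half the silhouette, and at extreme viewing
angles; the scene generator exposes a mild ellipticity option
(axis ratio down to 0.9) precisely to probe that mismatch.

### Exact solver

Three points determine a circle through the linear system in the
algebraic parameters `(Dx, Dy, C)` of `x² + y² = Dx·x + Dy·y + C`:

    [x1 y1 1] [Dx]   [x1²+y1²]
    [x2 y2 1] [Dy] = [x2²+y2²]
    [x3 y3 1] [C ]   [x3²+y3²]

with `a = Dx/2`, `b = Dy/2`, `r = √(C + a² + b²)`. A sample is treated
as degenerate when the determinant magnitude falls below `1e-12` times
the cube of the sample's coordinate span (a scale-invariant collinearity
test). The batch RANSAC path evaluates the same system in closed
(Cramer) form, vectorised over all candidate triples.

### Consensus loop

`ransac_circle` draws 3 distinct indices per iteration from a private
`numpy` generator owned by the call (no global state; identical config
and seed give a bit-identical result). Degenerate triples are redrawn
and do not consume an iteration; if every draw is degenerate the fit
fails explicitly. Candidates are scored by the inlier count under
`|dᵢ − r| < ε`; ties break first on smaller mean absolute inlier
residual, then on the earlier iteration — deterministic and favouring
tighter fits. An `exhaustive` sampling mode enumerates every triple, and
is what the oracle-equivalence tests exercise against an independent
brute-force enumeration.

Defaults: 1000 iterations; `ε = 2.0 px` (Canny edges are about one
pixel thick, two pixels absorb the discretisation); `α = 1.0`. All are
configurable.

### Activation filter

The winning model assigns each point the logistic weight
`Y = 1/(1 + exp(α·(dᵢ − r)))`. As written, that expression is
one-sided: every point strictly inside the circle gets `Y > 0.5`
regardless of how far inside it lies, so thresholding it at 0.5 rejects
outward outliers but keeps all interior clutter. The package therefore
defaults to `residual_mode="absolute"`, which substitutes `|dᵢ − r|`
and filters symmetrically by closeness to the circle; the literal
`signed` form is retained as an option for fidelity.

Because the absolute-mode activation peaks at exactly 0.5 (attained at
`dᵢ = r`), a literal "retain Y > 0.5" rule would retain nothing. The
retention test is therefore expressed relative to the mode's peak
activation (supremum 1 for signed, 0.5 for absolute) and is inclusive:
`Y ≥ threshold × sup(Y)`. With the default threshold 0.5 this retains
the symmetric band `|dᵢ − r| ≤ ln 3 / α` (≈ 1.1 px at `α = 1`) in
absolute mode, and reproduces the one-sided interior rule exactly in
signed mode. Points on the circle are always retained.

### Refit

The retained points are refit by the algebraic (Kåsa) least-squares
circle — the linear least-squares solution of the same algebraic
system, optionally weighted by the activation values
(`refit_mode="activation_weighted"`). Kåsa fitting is slightly biased
towards smaller radii for short arcs, but on the near-complete,
tightly-banded contours that survive the activation filter the bias is
far below the pixel-quantisation noise; with exactly three points it
reduces to the exact solver.

## Imaging chain

Crop (half-open boxes, 0-based, x = column, y = row) → grayscale
(standard luminance weighting) → CLAHE → Gaussian blur → Canny →
edge-pixel enumeration in raster order. The contour is deliberately the
set of *all* edge pixels, not polygonal chains: the consensus fit
consumes an unordered point cloud and handles clutter itself.

None of the chain's parameters is dictated by the measurement model;
the defaults are standard practitioner settings, all exposed in
`PreprocessConfig`:

| parameter | default | notes |
|---|---|---|
| CLAHE clip limit | 2.0 | multiples of mean tile-histogram height |
| CLAHE tile grid | 8×8 | |
| Gaussian kernel | 5 (σ derived ≈ 1.1) | σ rule `0.3·((k−1)/2 − 1) + 0.8` |
| Canny low/high | 50/150 | 0–255 scale, relative to peak ROI gradient |

The Canny hysteresis thresholds are interpreted *relative to the
strongest smoothed gradient magnitude in the ROI* rather than as
absolute gradient values: ROI brightness and contrast vary strongly
across field conditions (and across the brightness augmentations), and
relative thresholds keep the silhouette edge detectable in all of them
while a constant image still yields an empty edge map. Detection boxes
are padded by 8 px before cropping: a detector's tight box touches the
silhouette, which would place the rim on the crop border where the edge
detector cannot localise it.

Images with an alpha channel are rejected rather than silently
flattened.

## Camera model and units

Depth rasters are 16-bit integers in millimetres with 0 marking invalid
returns (the common RGB-D convention); computation is in metres;
reported diameters in millimetres. Depth at the box centre is sampled
`nearest` by default — the literal "depth of the pixel centre point" —
with a `median3` mode (median of valid values in the 3×3
neighbourhood) for robustness against single-pixel dropouts. The
pixel-radius conversion uses the mean of `fx` and `fy` by default
(near-square pixels on RGB-D sensors); `fx`-only and `fy`-only are
options. Frame averaging uses a trailing window of exactly 10 frames by
default, configurable for longer evaluation series.

## Synthetic scenes

`generate_scene` emulates an orchard capture at the level the
measurement chain cares about:

* **geometry** — an anti-aliased disk of known centre and radius; the
  radius is derived from a metric diameter, depth and intrinsics by the
  same pinhole relation the measurement inverts (so projection
  round-trips are exact at zero noise);
* **camera** — default intrinsics follow a RealSense-class colour
  sensor (`fx = fy = 910 px` at 1280×720), rendered as the central
  640×480 crop of that frame;
* **appearance** — ripe-red fruit `(200, 55, 50)` with Lambert-like
  shading (0.85–1.0, brightest at the centre) over value-noise foliage
  clutter blending dark green `(45, 70, 40)` and soil brown
  `(70, 55, 35)`; the occluder is neutral gray-brown bark
  `(90, 78, 60)`;
* **occlusion** — the occluder covers an exact circular-segment
  fraction of the disk (chord offset solved from the segment-area
  equation), drawn as a half-plane rectangle or an ellipse from a
  random direction; the realised covered fraction is recorded in the
  truth manifest; fractions are capped below 0.5 because the method
  assumes a mostly visible contour;
* **sensor corruption** — additive Gaussian noise, salt-and-pepper
  flips, brightness offsets on RGB; Gaussian jitter (default 2 mm) on
  the fruit's depth; background depth 0.8–1.2 m behind the fruit,
  occluder 0.15 m in front.

What the generator does **not** emulate: specular highlights, soft
shadows, leaf silhouettes overlapping the contour with fruit-like
colour, motion blur, depth bleeding at silhouette boundaries, and
multi-fruit mutual occlusion. Passing the synthetic suites therefore
demonstrates the measurement chain's correctness and its robustness to
the modelled corruptions — not field performance on real orchard
imagery, where the detector and these unmodelled effects dominate.

The default study conditions used by the acceptance campaign are an
80 mm fruit at depths 0.8–1.5 m, occlusion up to 0.2, and Gaussian
noise σ up to 5 levels — a hand-sized apple at arm's reach of the
camera. Campaign sizes (100 scenes; 50-frame series) give stable means
while keeping a full run around half a minute on one CPU.

## Evaluation statistics

Per fruit, over a frame series: the *camera value* is the series mean;
the *deviation* is `|actual − camera|`; the *dispersion* is the mean of
`(frameᵢ − actual)²`. The dispersion is deliberately defined about the
*reference* value, not the series mean — it then decomposes as
(squared bias + per-frame variance) and upper-bounds the squared
deviation, which the property tests check. The published four-fruit
table this definition mirrors does not disambiguate the variance
estimator; the about-reference definition is fixed here and documented.
The error range reports the min and max per-fruit deviation rounded
half-up to 2 decimals.

The baseline detector (red-excess threshold at 40 levels + 8-connected
components, area ≥ 150 px², confidence = component solidity) exists so
the pipeline runs end-to-end without trained weights; it is plumbing,
not a contribution, and any detector can replace it through the
`Detection` contract or a replayed CSV/JSON file.

## Known limitations

* The circle model under-estimates the diameter of visibly elliptical
  fruit (by construction it reports a compromise radius).
* Kåsa refitting is biased for very short retained arcs (severe
  occlusion); the occlusion cap keeps the method inside its validity
  region.
* Depth is point-sampled at the box centre; a specular or occluded
  centre pixel falls back to `median3` only if selected.
* The activation filter's retained band (`ln 3 / α` at the default
  threshold) is narrower than the RANSAC inlier tolerance ε; with very
  noisy contours, raising `α` tightens and lowering it loosens the
  refit set.
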