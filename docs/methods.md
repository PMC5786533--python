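# Methods

This note documents the models and procedures implemented in `lidarcanopy`,
the parameters that matter, the design choices made where several defensible
options existed, and the known limits of what the synthetic tests
demonstrate.

## Coordinate conventions

All computation happens in a local ENU metric frame: x is the platform
travel direction, y cross-track, z up. GPS fixes are consumed directly in
this frame; geodetic conversion is out of scope. The scanner sweeps a
vertical plane perpendicular to travel. Beam angle θ is measured so θ = 90°
is nadir; a beam of range r from sensor position p lands at
`(p_x, p_y + r cos θ, p_z − r sin θ)`. Angles are degrees at every
interface and converted to radians exactly once.

## Scan simulation

The simulator is the package's ground-truth source. A scene is a flat
ground plane carrying parametric solids — hemisphere, ellipsoid cap
(upper half-ellipsoid), box, cone — each with closed-form maximum height,
footprint area and volume; optional small spherical "weed" blobs detached
from every canopy footprint; and optional vertical enclosure walls at
± a cross-track half-width. Shape footprints may not overlap (checked with
polygon intersection) so per-shape truth stays well defined.

Each beam is an exact ray-cast: the returned range is the distance to the
*nearest* intersection among ground, solids, weeds and walls. This matters:
it reproduces the self-occlusion of a real single-viewpoint scanner (see
*Observability limits* below). No-hit beams carry the scanner's maximum
range (80 m) as a sentinel, mirroring real hardware, and are skipped during
reconstruction.

Default pass parameters reproduce the targeted field protocol: platform
speed 0.5 m/s, GPS at 5 Hz, scanner at 50 Hz with a 190° aperture at 1/3°
resolution (571 beams/frame, nadir included), sensor 2.4 m above ground.
Note 1/3° — not the nominally quoted 0.33° — is the value consistent with
571 beams over 190°. Range noise is i.i.d. Gaussian on range only
(sd 0.005 m by default, the close-range statistical ranging error typical
of this scanner class); angular jitter, beam divergence, multi-echo
returns, particle filtering and wind-induced motion are not modelled, so
the noise model keeps every oracle analytic. GPS fixes are exact platform
positions: GPS error (≈1 cm RTK) is small against plot dimensions and
omitting it keeps the reconstruction oracle exact. All randomness flows
from one `numpy` generator seeded by the pass config; identical configs are
bit-identical.

## Reconstruction

Frames are assigned to GPS intervals by timestamp (a frame exactly on a fix
time opens that fix's interval); frames before the first fix are dropped
and counted. With α = f_LiDAR/f_GPS (an integer, validated), the j-th frame
of interval i is placed at `P_i + j(P_{i+1} − P_i)/α + D_offset`, i.e.
constant speed within each interval, with `D_offset` the fixed
LiDAR-to-GPS lever arm applied to the whole frame. Frames after the last
fix are *extrapolated* at the last interval's velocity rather than silently
discarded; the count is logged. The streams are assumed to share one clock;
a constant clock-offset knob is exposed for rigs where they do not.

The enclosure filter is a pure range-interval test on the raw beam range
(accepted interval default 0.5–3.0 m). It removes the no-hit sentinel,
near-sensor structure, and wall returns, and simultaneously bounds the
cross-track extent of the ground — which is why plot cropping needs to cut
along-track only. A consequence worth knowing: range alone can only
separate wall returns when the walls lie outside the accepted interval
(farther than the longest crop/ground return, or nearer than the shortest);
demo scenes place walls at ±3.2 m accordingly.

With zero noise the whole chain is exact: reconstructed points coincide
with the simulator's analytic ray intersections to < 1e-9 m (tested at
1e-6), and point-count conservation (valid beams − filtered = output) is
asserted per run.

## Segmentation

**Plot cropping** keeps points in the plot's half-open along-track interval
`[col·(width+alley), +width)`; boundary points go to the lower-index plot.
Defaults encode a 16 × 8 grid of 3.05 m plots with 1.52 m row spacing and
1.83 m alleys.

**Ground plane.** Standard RANSAC: 1000 seeded 3-point hypotheses (the
source gives no parameter values; 1000 iterations makes the probability of
missing a ≥60%-inlier plane negligible), inlier threshold 0.03 m, best
hypothesis refined by total least squares (SVD) on its inliers, normal
oriented upward, mask recomputed against the refined plane. Run per plot by
default (configurable) so gentle field tilt cannot bias distant plots.
Points more than the threshold above the plane become the plant cloud and
gain a height-above-plane attribute; everything else is ground.

**Weed removal.** Single-linkage connected components under an inter-point
distance tolerance (default 0.05 m, ≈4× the default point spacing so a
continuous canopy never fragments). Components are found on a KD-tree
radius graph, which is exactly equivalent to the naive all-pairs linkage
(property-tested against a brute-force union-find oracle). Retention rule:
the largest component is always kept; any other component is kept iff it
has ≥ 30 points *and* its centroid lies at least 0.1·plot-width inside the
plot's along-track interval. "Attachment" of a weed to the canopy is not
observable from the data alone, so the rule operationalizes it as
size-plus-centrality; both knobs are configurable.

**Plane normalization** re-expresses clouds in the plane frame (u =
projection of travel axis onto the plane, z = height above plane) so that
traits and the bounding box are axis-aligned with the row even on tilted
ground.

## Traits

A height filter (default 0.05 m) removes residual near-ground returns
before *all three* traits; the source protocol mentions this threshold for
the volume computation, and applying it uniformly keeps the traits
mutually consistent (per-trait override available).

**Canopy height** uses linear interpolation between order statistics
(`numpy.quantile`, method "linear") at the 85, 88, 91, 94, 97 and 100th
percentiles. A histogram-based quantile would need an arbitrary bin width;
interpolated order statistics are bin-free, monotone in the percentile and
order-invariant, and the 100th percentile equals the apex height exactly.

**Projected canopy area** projects points onto the fitted plane and takes
the area of the alpha-shape: Delaunay triangles with circumradius ≤ α,
α defaulting to 5× the median nearest-neighbour spacing of the projected
points (scales automatically with sampling density). The boundary visible
in field data is concave, which is why a concave hull is the default; an
occupancy-grid method (cell 0.02 m) is provided as a cross-check and is
monotone under point-set inclusion. The alpha-shape area never exceeds the
convex-hull area; both never exceed the bounding-box area. Degenerate
inputs (fewer than 3 distinct projected points, collinear projections) are
errors.

**Plant volume** is the trapezoidal rule applied twice. Points are
regrouped into per-frame profiles via the stored frame index; samples are
ordered by beam sweep (falling back to a y-sort for imported clouds without
beam order); the scan position l is the frame's along-track coordinate.
`A_i = Σ (y_{j+1} − y_j)(z_{j+1} + z_j)/2` per scan, then
`PV = Σ (l_{i+1} − l_i)(A_{i+1} + A_i)/2` across scans. The rule is exact
(machine precision) for piecewise-linear profiles sampled at their knots —
property-tested — and empirically converges on simulated solids as beam
and scan spacings shrink. Scans with fewer than two points contribute zero;
empty plots yield a null trait record rather than an error.

### Observability limits

A single overhead viewpoint cannot see below the tangent circle of a
convex solid. For a hemisphere of radius r scanned from height h, the
visible cross-track half-width in the scan plane through the apex is
`r·sqrt(1 − (r/h)²)` — 0.909 m for r = 1 m, h = 2.4 m — further reduced
(to ≈0.87 m) by the finite 1/3° beam spacing at grazing incidence. At
default densities this bounds full-pipeline recovery to about −12% of the
analytic footprint π and −6% of the analytic volume 2π/3 (zero-noise
measurements; halving both spacings gives −8.7%/−4.1%, converging to the
analytic occlusion limits of −6.5%/−3%). Apex height is unaffected
(recovered within noise, ≈0.016 m at the 0.005 m noise default). Flat-top
solids have no such skirt: the test box (2 × 1 × 0.5 m) recovers its
volume within 0.6%. Real canopies are scanned under exactly this geometry,
so field PCA/PV should likewise be read as *visible-surface* measures —
the tests quantify the gap rather than hide it.

## Growth and statistics

The three-parameter logistic `y(t) = x0·xn/(x0 + (xn − x0)e^{−τ(t−T)})`
(y(T) = x0 identically; y → xn as t → ∞ for τ > 0) is fitted by bounded
non-linear least squares (`scipy.optimize.least_squares`, positivity
bounds, tolerances 1e-14) with initialization x0 ← first observation,
xn ← series maximum, τ ← 0.1/day. T defaults to the first observation day
(45 DAP in the reference calendar). Confidence intervals are linearized
(t-quantile × Jacobian standard errors); a residual bootstrap is available
when the Gaussian approximation is suspect. Non-convergence and
unidentifiable τ (flat series, x0 ≈ xn) are *flags on the results object*,
never silent failures. By default the full series is fitted through any
late defoliation decline (the logistic plateau absorbs it); a
`truncate_at_max` flag cuts the series at its maximum instead. Noise-free
parameter recovery is exact to ≤1e-6 relative error across a parameter
grid; at 2% observation noise over 8 dates the mean bias over 50
replicates stays below 5%.

Growth rates are interval difference quotients labelled P1–P8 when the
dates match the canonical sampling calendar (43, 45, 52, 67, 74, 88, 95,
102, 109 DAP). Cultivar effects use one-way fixed-effects ANOVA per trait
and date (type-I error calibrated: null rejection 0.05 ± 0.02 over 1000
simulations). Trait–yield association is per-date simple OLS R², per
cultivar or pooled; under independence E[R²] = 1/(n−1), verified at n = 32.
P-values are reported uncorrected across dates and traits, matching common
practice for these screens; apply Benjamini–Hochberg externally if desired.
Season fits default to cultivar means over plots (both pooled-plot and
per-plot fitting are possible through the model class).

## Synthetic season tables

`simulate_field_season` emulates a four-cultivar trial (32 plots each,
8 sampling dates) whose trait trajectories follow per-plot logistic curves:
cultivar asymptotes (CH 1.08/1.08/0.96/0.88 m; PCA 2.73/2.23/2.47/2.34 m²;
PV 2.75/2.17/2.11/1.59 m³), a plot random effect (8% CV), τ ≈ 0.12/day
with 10% plot scatter, 4% multiplicative observation noise, and mean
yields of 928.5/781.6/954.2/937.2 g/plot coupled to the plot's volume
asymptote so that within-cultivar late-season trait–yield R² lands around
0.5–0.8 while pooled R² is weaker — the qualitative pattern seen in field
trials. What these tables do *not* emulate: spatial field trends, serial
correlation of measurement error across dates, or weather shocks; passing
statistics on them shows the estimators are correct and calibrated, not
that any particular field will show these effect sizes.

## Problem sizes and numerical choices

Desk-scale defaults keep every check fast while staying at the field
protocol's densities: recovery scenes use a 4 m pass (401 frames × 571
beams ≈ 2·10⁵ rays), RANSAC robustness uses 20 seeds × 1000 points with
40% outliers, calibration checks use 1000 (ANOVA) and 500 (R²)
simulations, and oracle-equivalence checks use 50 instances of 200-point
clouds. Ties at plot boundaries go to the lower plot; quantile ties follow
numpy's linear rule; the RANSAC winner is the first hypothesis reaching
the best inlier count under the seeded sampling order, making every run
reproducible from its seed.

## Worked-example snippet

The README's printed numbers come from:

```python
import lidarcanopy as lc

scene = lc.build_scene(shapes=[{"kind": "hemisphere", "center": [2.0, 0.0], "radius": 1.0}])
fixes, frames, truth = lc.simulate_pass(scene, lc.PassConfig(seed=1), (0.0, 4.0, 0.0))
print(f"{len(fixes)} GPS fixes, {len(frames)} frames of {frames[0].n_beams} beams")
cloud, stats = lc.reconstruct_cloud(fixes, frames, lc.SensorConfig())
plane, _ = lc.fit_ground_ransac(cloud, seed=1)
plant, ground = lc.remove_ground(cloud, plane)
plant, _ = lc.cluster_denoise(plant, tolerance=0.05, min_cluster_size=30)
plant = lc.normalize_to_plane(plant, plane)
rec = lc.extract_traits(plant, lc.TraitConfig(), plot_id="hemi", dap=67)
print(f"max CH = {rec.max_ch:.3f} m   (truth 1.000)")
print("CH percentiles: " + ", ".join(f"p{p:g}={v:.3f}" for p, v in rec.ch_percentiles.items()))
print(f"PCA = {rec.pca:.3f} m^2 (visible-footprint truth <= pi = 3.142)")
print(f"PV  = {rec.pv:.3f} m^3 (solid truth 2pi/3 = 2.094)")
```

## Known limitations

- Single top view: organs under the canopy are invisible; PCA/PV are
  visible-surface measures (quantified above). Side views or multi-pass
  fusion are out of scope.
- The enclosure filter is range-only and cannot separate walls that fall
  inside the accepted range interval.
- The simulator's weeds are spheres and its canopies are smooth convex
  solids; leaf-level porosity, within-canopy gaps and wind blur are not
  modelled, so denoising and trait tests certify algorithmic correctness,
  not robustness to every field artefact.
- Growth fitting assumes independent observation errors across dates;
  plot-level serial correlation would narrow the reported intervals
  artificially.
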