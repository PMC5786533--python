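# lidarcanopy

High-throughput phenotyping of row-crop canopies with an overhead 2D
line-scan LiDAR and RTK-GPS. The package is aimed at field phenotyping and
plant-breeding groups who drive a scanner over plot trials and want, per plot
and sampling date: canopy-height percentiles, projected canopy area, and
plant volume — and, across a season, growth curves, growth rates, cultivar
effects, and trait–yield correlations.

## What it does

1. **Reconstruction.** A 2D LiDAR measures one vertical line scan (frame) of
   beam angle/range pairs per cycle at `f_LiDAR` (50 Hz); GPS fixes arrive at
   `f_GPS` (5 Hz). With `α = f_LiDAR / f_GPS` frames per GPS interval and
   constant speed within an interval, frame `k = iα + j` is georeferenced at

   ```
   p(k) = P_i + j · (P_{i+1} − P_i)/α + D_offset
   ```

   and each beam (θ, r) becomes the point
   `(x, y + r cos θ, z − r sin θ)` (θ = 90° is nadir). A range-interval
   filter removes enclosure-wall returns.

2. **Segmentation.** Plot clouds are cropped from the row by the field
   layout; the ground plane is fitted by RANSAC (3-point hypotheses,
   total-least-squares refinement) and removed; detached clusters (weeds)
   are dropped by single-linkage Euclidean clustering.

3. **Traits.** Per plot: canopy height CH as height-above-plane quantiles
   (85th…100th), projected canopy area PCA as the alpha-shape (concave
   boundary) of the ground-plane projection, and plant volume PV by the
   trapezoidal rule applied twice — across each scan profile,

   ```
   A_i = Σ_j (y_{j+1} − y_j)(z_{j+1} + z_j)/2,
   ```

   then along the travel direction, `PV = Σ_i (l_{i+1} − l_i)(A_{i+1} + A_i)/2`.
   A 0.05 m height filter removes residual near-ground returns first.

4. **Growth and yield analysis.** Per cultivar and trait, a
   three-parameter logistic model

   ```
   y(t) = x0·xn / (x0 + (xn − x0)·e^{−τ(t−T)})
   ```

   is fitted by non-linear least squares (`LogisticGrowth(...).fit()`
   returns a results object with estimates, Jacobian confidence intervals,
   `predict`, `summary`, `plot`). Interval growth rates are difference
   quotients `GR = (P_t − P_{t−Δt})/Δt`; cultivar effects use one-way
   ANOVA; trait–yield association uses per-date simple regression R².

5. **Simulation.** Because every stage needs ground truth, a seeded
   simulator scans analytic solids (hemisphere, ellipsoid cap, box, cone)
   resting on a plane, with optional weed blobs and enclosure walls, by
   exact ray casting plus Gaussian range noise; closed-form height,
   footprint area and volume come attached. A companion generator produces
   per-plot season trait/yield tables for the statistics stage.

## Worked example

Scan a 1 m hemisphere with the default sensor protocol (0.5 m/s, 5 Hz GPS,
50 Hz scanner, 190° aperture at 1/3°, 2.4 m above ground, 5 mm range noise)
and recover its traits:

```python
import lidarcanopy as lc

scene = lc.build_scene(shapes=[{"kind": "hemisphere", "center": [2.0, 0.0], "radius": 1.0}])
fixes, frames, truth = lc.simulate_pass(scene, lc.PassConfig(seed=1), (0.0, 4.0, 0.0))
cloud, stats = lc.reconstruct_cloud(fixes, frames, lc.SensorConfig())
plane, _ = lc.fit_ground_ransac(cloud, seed=1)
plant, ground = lc.remove_ground(cloud, plane)
plant, _ = lc.cluster_denoise(plant, tolerance=0.05, min_cluster_size=30)
plant = lc.normalize_to_plane(plant, plane)
rec = lc.extract_traits(plant, lc.TraitConfig(), plot_id="hemi", dap=67)
```

This prints (via the snippet in `docs/methods.md`):

```
41 GPS fixes, 401 frames of 571 beams
max CH = 1.016 m   (truth 1.000)
CH percentiles: p85=0.952, p88=0.962, p91=0.972, p94=0.982, p97=0.991, p100=1.016
PCA = 2.774 m^2 (visible-footprint truth <= pi = 3.142)
PV  = 1.972 m^3 (solid truth 2pi/3 = 2.094)
```

The apex height is recovered within the noise floor. PCA and PV sit a few
percent *below* the solid's closed forms — by construction: a single
overhead viewpoint cannot see a hemisphere below its tangent circle
(visible half-width `r·sqrt(1−(r/h)²)` = 0.909 m at h = 2.4 m), so part of
the skirt is occluded. See `docs/methods.md` for the quantitative limits.

Season-level analysis on synthetic tables:

```python
tdf, ydf = lc.simulate_field_season(seed=1)
sub = tdf[tdf.cultivar == "cultivar1"].groupby("dap")["max_ch"].mean().reset_index()
print(lc.LogisticGrowth(sub["dap"], sub["max_ch"], T=45).fit().summary())
```

```
Three-parameter logistic growth fit
  nobs = 8, T = 45 DAP, SSE = 0.000352583, converged = True
  param     estimate      std err       [0.025       0.975]
     x0     0.127838     0.005256     0.114327      0.14135
     xn      1.05717     0.004923      1.04452      1.06983
    tau     0.121791     0.002607      0.11509     0.128491
```

so cultivar 1's mean canopy height starts near 0.13 m at day 45, saturates
at 1.06 m, and grows at rate coefficient τ ≈ 0.12/day. Per-cultivar
trait–yield R² at 95 days after planting lands between 0.51 and 0.69 under
the default generator coupling.

## Command line

Every stage is also a subcommand over file-based interchange formats
(CSV streams, PLY/PCD clouds, CSV tables):

```sh
lidarcanopy simulate --config examples/hemisphere.yml --out run/
lidarcanopy pipeline --config examples/hemisphere.yml --out run/   # all stages
lidarcanopy simulate-season --out season/ --seed 1
lidarcanopy growth --traits season/traits.csv --yields season/yields.csv --out growth/
```

`pipeline` chains simulate → reconstruct → segment → traits and is
byte-identical to running the stages individually. All randomness derives
from the config (or `--seed`) so a run is reproducible from its config
alone.

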