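# dispersim

Simulation-based landscape connectivity from integrated step-selection
functions.

`dispersim` is for movement ecologists who have GPS telemetry of dispersing
animals and a set of habitat covariate rasters, and who want connectivity
maps that do not rest on the assumptions of least-cost paths (a known
endpoint) or circuit theory (memoryless random walks). It implements a
three-step pipeline:

1. **Movement model.** Each realized GPS step is contrasted with matched
   random steps (uniform turning angles, gamma step lengths fitted to the
   data) in a conditional logistic regression — an integrated step-selection
   function (ISSF). A step with covariates $x_1,\dots,x_n$ gets the
   selection score

   $$w(x) = \exp(\beta_1 x_1 + \cdots + \beta_n x_n),$$

   and the probability that step $i$ is the realized one in its stratum is
   $w(x_i)/\sum_j w(x_j)$. The model jointly captures the habitat kernel
   (covariate selection), the movement kernel (step length `sl`, `log_sl`,
   directional persistence `cos_ta`), and their interactions, selected by
   forward AIC search and validated with case–control k-fold
   cross-validation.

2. **Dispersal simulation.** The fitted model is inverted into an
   individual-based simulator: from each source point, 25 candidate steps
   are proposed from the movement kernel, scored with $w(x)$, and one is
   sampled by its probability. A randomized buffer zone around the study
   area absorbs boundary effects, and a checkpoint-based diagnostic reports
   when the ensemble has reached a steady state.

3. **Connectivity maps.** Simulated trajectories become (i) a *heatmap*
   (distinct trajectories traversing each cell), (ii) a *betweenness map*
   (trajectories are coarsened to a cell-to-cell transition network whose
   edge costs invert transition frequency, $\omega = \bar f / f$, and
   weighted node betweenness marks corridors and bottlenecks), and (iii) an
   *inter-patch connectivity* table (fraction of dispersers from each patch
   reaching each other patch, with mean steps to first arrival).

A path-selection function (PSF) validates any surface against held-out
paths: each observed path is contrasted with rigid-motion replicates
(random rotation and shift) in a one-covariate conditional logistic
regression; a positive coefficient means real paths track high
connectivity. A synthetic-data module generates landscapes, patches, and
GPS data from a *known* movement model so the entire pipeline is testable
without any field data.

Coordinates are projected meters throughout. Rasters are single-band
GeoTIFFs (georeferencing tags only, no CRS); patches and paths are GeoJSON;
fixes and trajectories are CSV.

## Worked example

```python
import numpy as np
import dispersim as ds
from dispersim import synth

# 1. a reproducible synthetic study: landscape, truth model, GPS fixes
scenario = synth.SyntheticScenario(seed=3, ncols=120, nrows=120,
                                   n_individuals=8, n_steps=100)
stack = ds.expand_with_buffer(synth.make_landscape(scenario), 10_000, seed=3)
truth = synth.make_truth_model(scenario, stack)
fixes = synth.generate_gps_data(scenario, stack, truth)

# 2. step 1 of the pipeline: fixes -> steps -> strata -> fitted ISSF
steps = ds.fixes_to_steps(ds.regularize_fixes(fixes))
gamma = ds.fit_gamma(steps["sl"])
strata = ds.build_strata(steps, stack, n_random=24, gamma=gamma,
                         rng=np.random.default_rng(1))
std, table = ds.standardize(strata, ["sl", "log_sl", "cos_ta"] + stack.names)
model = ds.fit_clogit(std, ["sl", "log_sl", "cos_ta", "water", "woodland",
                            "shrub", "human"],
                      gamma=gamma, standardization=table, n_random=24)
print(model.summary().round(3))

# 3. step 2: release dispersers and simulate
patches = synth.make_patches(scenario, k=4)
sources = ds.place_source_points(patches, stack, n_patch=100, n_buffer=0,
                                 min_area_km2=50, rng=np.random.default_rng(2))
ensemble = ds.simulate_ensemble(sources, model, stack,
                                ds.SimulationConfig(n_steps=100, seed=4))
print(f"boundary contact fraction: {ensemble.boundary_fraction:.3f}")

# 4. step 3: connectivity maps
heat = ds.heatmap(ensemble.trajectories,
                  ds.grid_from_extent(stack.grid.extent, 1000.0))
net = ds.build_network(ensemble.trajectories,
                       ds.grid_from_extent(stack.grid.extent, 2500.0))
bmap = ds.betweenness(net)
table_ip = ds.interpatch(ensemble.trajectories, patches)
print(f"max cell traversal count: {heat.counts.max()}")
print(f"max betweenness: {np.nanmax(bmap.scores):.0f}")
print(table_ip.sort_values("fraction", ascending=False)
             .head(3).round(2).to_string(index=False))
```

This prints:

```
           beta     se      z      p
sl        0.121  0.045  2.654  0.008
log_sl    0.088  0.055  1.601  0.109
cos_ta    0.405  0.045  9.015  0.000
water    -0.565  0.088 -6.422  0.000
woodland -0.311  0.067 -4.654  0.000
shrub     0.210  0.066  3.172  0.002
human    -0.242  0.079 -3.083  0.002
boundary contact fraction: 0.990
max cell traversal count: 30
max betweenness: 12109
 source  target  n_origin  n_success  fraction  mean_steps
patch_2 patch_1        18         15      0.83       26.40
patch_1 patch_0        31         20      0.65       34.05
patch_0 patch_1        51         28      0.55       40.57
```

The coefficient table is the fitted ISSF on the standardized scale: this
virtual species moves directionally (`cos_ta` > 0), avoids water, woodland
and human influence, and selects shrub/grassland — matching the
data-generating model. Almost every simulated disperser leaves the small
30 km core at least once (boundary contact 0.99), which is why the buffer
zone matters at this scale. The inter-patch table reads, e.g., 83% of the
18 dispersers released in `patch_2` reached `patch_1`, after 26 four-hour
steps on average.

A `dispersim` command-line tool wraps the same pipeline for shell use
(`dispersim fit / simulate / maps / validate / synth`; see `--help`).

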