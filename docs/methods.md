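# Methods

## The movement model

The package models animal movement as a discrete-time step process on a
fixed observation schedule (default 4 h). A *step* is the straight line
between two consecutive fixes; its covariates are the step length `sl` (m),
`log_sl`, the cosine of the relative turning angle `cos_ta` (directional
persistence), a binary `low_activity` flag (local clock time in
[09:00, 17:00), the hot midday hours when many large mammals rest), and the
unweighted mean of each habitat raster along the step.

Each realized step is paired with `n_random` (default 24) random steps
sharing its start point and time: turning angles uniform on (−π, π) and
lengths from a gamma distribution fitted by maximum likelihood to the
realized step lengths. Sampling angles uniformly does not assume uniform
turning — directionality is estimated through `cos_ta` in the model; the
same holds for the gamma proposal, whose mismatch with the true step-length
kernel is absorbed exactly by the `sl` and `log_sl` coefficients (the ratio
of two gamma densities is `exp(a·log sl + b·sl)` up to a constant).
`MovementModel.updated_gamma()` exposes the corrected kernel
gamma(k + b_log_sl, 1/(1/θ − b_sl)).

The stratum of one realized and its random steps enters a fixed-effects
conditional logistic likelihood: the probability that step *i* was realized
is softmax of the linear predictors within its stratum. The likelihood,
analytic gradient, and observed-information Hessian are evaluated with
grouped reductions; optimization is BFGS from β = 0 followed by Newton
polishing until the gradient ∞-norm is below 1e-6. Coefficient covariance
is the inverse observed information. Covariates with no within-stratum
variation (for example a bare `low_activity` main effect — it is constant
across a stratum's candidate steps) cancel out of the conditional
likelihood; the fit refuses them with a named error rather than returning a
singular information matrix, so such covariates should enter through
interactions. Mixed-effects random slopes are deliberately out of scope;
the fixed-effects conditional likelihood is the exact analogue for a single
population-level coefficient vector, which is all the simulator consumes.

Continuous covariates are standardized to zero mean and unit sd pooled over
all (realized + random) steps; the (mean, sd) table is stored on the model
so simulation operates on the fitted scale, and `beta_raw()` converts main
effects back to raw units (a coefficient on (x−m)/s is s times the raw
coefficient).

Model structure is chosen by greedy forward AIC search from a base model
over movement-by-habitat interaction candidates
({sl, log_sl, cos_ta} × {habitat, low_activity} plus cos_ta:sl and
cos_ta:log_sl). Predictive ability is assessed with case–control k-fold
cross-validation (default k = 5): held-out realized steps are ranked among
their stratum by predicted score (rank 1 = best, ties broken uniformly at
random), and the Spearman correlation between rank and rank frequency is
summarized by its mean and 95% percentile interval over folds, against a
null with uniformly drawn ranks. A predictive model yields a strongly
negative correlation whose interval separates from the null's.

## The dispersal simulator

Simulation inverts the fitted model: from a source point with a uniform
random initial heading, each iteration proposes `n_candidates` (default 25)
random steps from the movement kernel, extracts and standardizes their
covariates, scores them with the model, and samples one step by its
within-stratum probability. The clock advances one fix interval per step
and drives `low_activity`; each trajectory starts at a random slot of the
4-h schedule so the flag alternates realistically.

Boundary handling follows the buffer-zone approach: the covariate stack is
expanded by a buffer (paper-scale 100 km; desk-scale runs here use 10 km)
whose cells are filled i.i.d. by resampling each layer's non-missing core
cells, and any candidate step leaving the buffered grid is redrawn
individually (cap 10,000, then an error naming the position). Because the
grid extent is convex, endpoint containment implies segment containment.
Ensembles run one trajectory per source point on independent random
substreams spawned from the master seed, so results are reproducible and
independent of execution order; the fraction of trajectories leaving the
core extent at least once is reported as a boundary-effect diagnostic.

Steady state is diagnosed with randomly placed square checkpoints (default
5 km): for increasing subsample sizes m, trajectories are repeatedly
subsampled without replacement and the 95% prediction-interval width of
each checkpoint's traversal frequency (binary: a trajectory either
intersects the checkpoint or not) is recorded; the ensemble is converged at
the smallest m with all widths below 0.01.

## Connectivity maps

*Heatmap*: every trajectory contributes at most once per cell; cells are
found by an exact supercover traversal of each step segment (every cell the
segment intersects, using the half-open cell convention), clipped to the
map grid. *Transition network*: consecutive step endpoints are mapped to
cells of a coarser grid (default 2.5 km); directed transitions between
distinct cells are counted over all trajectories, and edge cost inverts
frequency, ω = mean(f)/f, so an averagely used edge costs 1. Long steps
link their endpoint cells directly by default (a `supercover` switch routes
them through the full cell sequence instead). Node betweenness is computed
on the directed weighted graph by Brandes' algorithm with Dijkstra
(networkx), equal-cost paths sharing credit fractionally; scores are
reported raw (any display transform is left to plotting). *Inter-patch
connectivity*: a trajectory from source patch s succeeds for target t when
any of its positions (step endpoints, consistent with the 4-h observation
model) falls inside t; the first such step index enters the mean dispersal
duration. Buffer-released trajectories are never origins.

## PSF validation

Observed paths are contrasted with rigid-motion nulls: rotation by
α ~ U(−π, π) about the path's first vertex (the paper-style transform does
not fix a pivot; the first vertex is the package's choice), then a shift of
d ~ U(0, d_max) in a direction φ ~ U(−π, π). Shape is preserved exactly.
Each path's connectivity is the mean surface value over its supercover cell
set; nulls without surface overlap are dropped from their stratum, strata
whose observed path has no overlap are dropped entirely (logged). A
one-covariate conditional logistic fit returns the selection coefficient
with its Wald SE.

## The synthetic-data generator

`SyntheticScenario` fixes the study conditions: a 300 × 300-cell grid at
250 m (75 km × 75 km) by default, five layers emulating the structure of
savanna covariates — binary water from thresholded smoothed Gaussian noise
(12% cover), its Euclidean distance transform in meters, mutually exclusive
autocorrelated woodland and shrub/grassland classes (30% each), and a
continuous non-negative human-influence gradient with noise; rectangular
patches whose areas straddle the 700 km² source-eligibility threshold; and
GPS data produced by simulating a known movement model (defaults:
cos_ta +0.5, water −1.0, woodland −0.4, shrub +0.4, human −0.5 on the
layer-standardized scale; gamma step lengths k = 0.37, θ = 6308 m, the
field-typical long-tailed kernel) on the buffered landscape. Fixes follow
the 4-h schedule with uniform ±7.5-min timestamp jitter — large enough to
exercise the ±15-min regularization tolerance, small enough that
consecutive lags always stay within it, keeping dropout-free data exactly
recoverable — and independent per-fix dropout (default 10%).

What the generator does *not* emulate: temporal covariate dynamics
(flooding), spatially structured buffer covariates, inter-individual
differences or interactions, mortality, and GPS position error. Passing
tests therefore demonstrate statistical self-consistency of the pipeline —
the fit recovers the data-generating process and the maps faithfully
summarize the simulated ensembles — not robustness to those real-data
features.

`simulate_strata` additionally generates conditional-logit strata directly
(i.i.d. standard-normal covariates, realized step drawn by softmax
probability) for estimator calibration independent of the landscape
machinery.

## Numerical and design choices

- Cells are half-open ([x, x+res) × (y−res, y], top-closed) so every point
  maps to exactly one cell; supercover traversal takes midpoints of the
  segment's crossing-parameter intervals, which agrees with arbitrarily
  dense point sampling.
- Along-step averages use evenly spaced point sampling at spacing ≤ res/2
  inclusive of both endpoints (at least 2 points), which bounds
  discretization error below one cell and makes the average symmetric under
  direction reversal. Missing cells are excluded from averages and from
  buffer resampling pools.
- Softmax probabilities subtract the within-stratum maximum before
  exponentiation, so linear predictors of ±800 remain finite.
- Step lengths drawn from the gamma proposal are floored at 1 nm to keep
  `log_sl` finite (the gamma density at 0 is improper for k < 1).
- Zero-length realized steps are dropped (log sl undefined) and break the
  heading chain; post-gap steps are kept but excluded from strata because
  their turning angle is undefined.
- Rank ties in cross-validation are broken uniformly at random with the
  run's generator; the fold count k = 5 and reps default to 100.
- AIC = 2p − 2 logL; forward selection stops when no candidate improves the
  current AIC, and candidates whose fit fails are skipped with a warning.

## Problem sizes

Desk-scale defaults were chosen so the full loop runs in seconds to
minutes: the acceptance pipeline uses 30 individuals × 120 steps of GPS, a
200-trajectory ensemble of 150 steps over the 75 km landscape with a 10 km
buffer, 200 checkpoints, and a 15-path PSF. Estimator calibration uses
2,000 directly simulated strata per seed; end-to-end recovery uses
40 × 150 GPS steps, where raw-scale coefficients return to the
data-generating values within sampling error. Paper-scale studies (10⁴–10⁵
trajectories of 2,000 steps over ~10⁶ km²) use the same code paths; the
simulator costs roughly 0.3 ms per step per disperser.

## Known limitations

- Static landscapes only; covariates do not change as dispersers move.
- One population-level coefficient vector (no per-individual random
  slopes); the `MovementModel` API leaves room for a per-individual
  coefficient table.
- The network's ω uses *edge* transition frequency (not per-cell traversal
  frequency), and betweenness is computed on the directed network; both are
  documented choices where conventions differ.
- Inter-patch success tests step endpoints, so a patch crossed entirely
  within one step is not counted — consistent with the observation model
  but a real undercount for very small patches.
- PSF nulls are not constrained to the study area; strata losing all
  overlap are dropped rather than re-randomized.
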