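"""Synthetic scenarios with the statistical structure the pipeline assumes.

The generator emulates the structure of dispersal GPS studies: a handful of
habitat covariate layers on a 250 m grid (binary water with a distance
transform, two mutually exclusive autocorrelated vegetation classes, a
continuous human-influence gradient), habitat patches whose areas straddle
the source-eligibility threshold, and GPS fixes produced by simulating a
*known* movement model on the landscape, sampled on a 4-h schedule with
timestamp jitter and random fix dropouts. Because the data-generating model
is known, the full pipeline can be checked for parameter recovery without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .issf import GammaStepLength, MovementModel
from .landscape import CovariateStack, GridSpec, crop_to_core
from .simulator import SimulationConfig, SourcePoint, simulate_trajectory

#: layer names produced by make_landscape
LAYERS = ("water", "dist_water", "woodland", "shrub", "human")


@dataclass
class SyntheticScenario:
    """Recipe for one reproducible synthetic study.

    The default grid (300 x 300 cells at 250 m, i.e. 75 km x 75 km) is large
    enough that patch areas can straddle the 700 km^2 source-eligibility
    threshold. ``truth_beta`` holds the data-generating coefficients on the
    standardized scale of ``make_truth_model``.
    """

    seed: int = 0
    ncols: int = 300
    nrows: int = 300
    res: float = 250.0
    smooth_sigma: float = 4.0
    water_frac: float = 0.12
    woodland_frac: float = 0.30
    shrub_frac: float = 0.30
    gamma: GammaStepLength = field(default_factory=lambda: GammaStepLength(0.37, 6308.0))
    truth_beta: dict[str, float] = field(
        default_factory=lambda: {
            "cos_ta": 0.5,
            "water": -1.0,
            "woodland": -0.4,
            "shrub": 0.4,
            "human": -0.5,
        }
    )
    n_individuals: int = 20
    n_steps: int = 150
    fix_interval: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(hours=4))
    jitter: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(minutes=7.5))
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.ncols < 50 or self.nrows < 50:
            raise ValueError("grid must be at least 50 x 50 cells")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(x0=0.0, y0=self.nrows * self.res, res=self.res,
                        ncols=self.ncols, nrows=self.nrows)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")


def make_landscape(scenario: SyntheticScenario) -> CovariateStack:
    """Five covariate layers with controllable patchiness (seed-reproducible)."""
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.nrows, scenario.ncols)
    f_water = _smooth_field(rng, shape, scenario.smooth_sigma)
    f_veg = _smooth_field(rng, shape, scenario.smooth_sigma)
    f_hum = _smooth_field(rng, shape, scenario.smooth_sigma)
    water = (f_water > np.quantile(f_water, 1 - scenario.water_frac)).astype(float)
    dist_water = ndimage.distance_transform_edt(water == 0) * scenario.res
    hi = np.quantile(f_veg, 1 - scenario.woodland_frac)
    lo = np.quantile(f_veg, scenario.shrub_frac)
    woodland = ((f_veg >= hi) & (water == 0)).astype(float)
    shrub = ((f_veg <= lo) & (water == 0)).astype(float)
    gradient = np.tile(np.linspace(0.0, 1.0, scenario.ncols), (scenario.nrows, 1))
    human = np.clip(gradient + 0.3 * f_hum, 0.0, None)
    return CovariateStack(
        grid=scenario.grid,
        layers={
            "water": water,
            "dist_water": dist_water,
            "woodland": woodland,
            "shrub": shrub,
            "human": human,
        },
    )


def make_patches(scenario: SyntheticScenario, k: int = 5) -> pd.DataFrame:
    """Disjoint rectangular patches with areas straddling 700 km^2.

    Patch areas are fixed fractions of the core area (largest first) so that
    at least one patch exceeds and one falls below the eligibility threshold
    on the default grid; positions take a small seeded jitter inside a slot
    grid, keeping patches disjoint.
    """
    if k > 6:
        raise ValueError("at most 6 patches supported")
    rng = np.random.default_rng(scenario.seed + 1)
    xmin, ymin, xmax, ymax = scenario.grid.extent
    W, H = xmax - xmin, ymax - ymin
    fracs = np.array([0.16, 0.10, 0.06, 0.04, 0.025, 0.015])[:k]
    # 2 x 3 slot grid; one patch per slot keeps them disjoint
    slots = [(r, c) for r in range(3) for c in range(2)]
    rng.shuffle(slots)
    sx, sy = W / 2, H / 3
    rows = []
    for idx, frac in enumerate(fracs):
        area = frac * W * H
        side = np.sqrt(area)
        side_y = min(side, sy * 0.98)
        side_x = min(area / side_y, sx * 0.98)
        r, c = slots[idx]
        margin_x = max(sx - side_x, 0.0)
        margin_y = max(sy - side_y, 0.0)
        x = xmin + c * sx + rng.uniform(0.1, 0.9) * margin_x
        y = ymin + r * sy + rng.uniform(0.1, 0.9) * margin_y
        geom = shapely.box(x, y, x + side_x, y + side_y)
        rows.append(
            {
                "id": f"patch_{idx}",
                "geometry": geom,
                "area_km2": geom.area / 1e6,
            }
        )
    return pd.DataFrame(rows)


def make_truth_model(scenario: SyntheticScenario, stack: CovariateStack) -> MovementModel:
    """Data-generating ISSF with known coefficients.

    Habitat covariates are standardized with their core-cell means and sds
    (so the truth coefficients live on a well-defined scale); movement
    covariates stay raw. ``cos_ta`` induces directional persistence on top
    of the uniform turning-angle proposal.
    """
    core = crop_to_core(stack)
    table = {}
    for name, arr in core.layers.items():
        if name in scenario.truth_beta:
            v = arr[np.isfinite(arr)]
            sd = float(v.std())
            if sd == 0:
                raise ValueError(f"layer {name!r} is constant; cannot standardize truth")
            table[name] = (float(v.mean()), sd)
    terms = list(scenario.truth_beta)
    missing = [t for t in terms if ":" not in t and t not in
               list(stack.layers) + ["sl", "log_sl", "cos_ta", "low_activity"]]
    if missing:
        raise ValueError(f"truth terms {missing} not available on the stack")
    return MovementModel(
        terms=terms,
        beta=np.array([scenario.truth_beta[t] for t in terms], dtype=float),
        standardization=table,
        gamma=scenario.gamma,
        n_random=24,
    )


def generate_gps_data(
    scenario: SyntheticScenario,
    stack: CovariateStack,
    truth: MovementModel | None = None,
) -> pd.DataFrame:
    """GPS fixes from trajectories simulated under the truth model.

    One trajectory per individual, started uniformly inside the core extent
    (inset by one mean step length), sampled every ``fix_interval`` with
    uniform timestamp jitter, each fix independently deleted with
    probability ``dropout_rate``.
    """
    if truth is None:
        truth = make_truth_model(scenario, stack)
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 2)))
    xmin, ymin, xmax, ymax = stack.core_extent
    inset = min(truth.gamma.mean, (xmax - xmin) / 4)
    config = SimulationConfig(
        n_candidates=truth.n_random + 1,
        n_steps=scenario.n_steps,
        seed=scenario.seed,
    )
    jit_s = scenario.jitter.total_seconds()
    frames = []
    base = pd.Timestamp("2021-06-01 00:00:00")
    for ind in range(scenario.n_individuals):
        src = SourcePoint(
            x=rng.uniform(xmin + inset, xmax - inset),
            y=rng.uniform(ymin + inset, ymax - inset),
            origin="synthetic",
        )
        t0 = base + pd.Timedelta(days=ind) + pd.Timedelta(
            hours=int(rng.choice([0, 4, 8, 12, 16, 20]))
        )
        traj = simulate_trajectory(src, truth, stack, config, rng)
        n = len(traj.positions)
        t = (
            t0
            + scenario.fix_interval * np.arange(n)
            + pd.to_timedelta(rng.uniform(-jit_s, jit_s, size=n), unit="s")
        )
        frame = pd.DataFrame(
            {
                "individual": f"ind_{ind}",
                "t": t,
                "x": traj.positions[:, 0],
                "y": traj.positions[:, 1],
            }
        )
        if scenario.dropout_rate > 0:
            frame = frame[rng.uniform(size=n) >= scenario.dropout_rate]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_strata(
    n_strata: int,
    beta,
    n_random: int = 24,
    rng: np.random.Generator | None = None,
    columns: list[str] | None = None,
    interaction_columns: int = 0,
) -> pd.DataFrame:
    """Directly simulated conditional-logit strata with known coefficients.

    Candidate covariates are i.i.d. standard normal; the realized step in
    each stratum is drawn with probability proportional to exp(beta . x).
    ``beta`` maps term names (products allowed, e.g. ``"a:b"``) to true
    values; extra independent columns can be added as selection-neutral
    noise. Useful for estimator calibration and selection-recovery checks.
    """
    rng = np.random.default_rng(rng)
    if not isinstance(beta, dict):
        beta = {f"x{k}": float(b) for k, b in enumerate(np.atleast_1d(beta))}
    base_cols = set()
    for term in beta:
        base_cols.update(term.split(":"))
    if columns is not None:
        base_cols.update(columns)
    base_cols = sorted(base_cols)
    for k in range(interaction_columns):
        base_cols.append(f"noise{k}")
    m = n_random + 1
    data = {c: rng.standard_normal(n_strata * m) for c in base_cols}
    eta = np.zeros(n_strata * m)
    for term, b in beta.items():
        parts = term.split(":")
        x = np.ones(n_strata * m)
        for p in parts:
            x = x * data[p]
        eta += b * x
    eta = eta.reshape(n_strata, m)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    pick = (p.cumsum(axis=1) > rng.uniform(size=(n_strata, 1))).argmax(axis=1)
    case = np.zeros((n_strata, m), dtype=int)
    case[np.arange(n_strata), pick] = 1
    frame = pd.DataFrame(data)
    frame.insert(0, "case", case.ravel())
    frame.insert(0, "stratum", np.repeat(np.arange(n_strata), m))
    return frame
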