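"""Step 2: individual-based dispersal simulation from a fitted ISSF.

Virtual dispersers are released at source points with a random initial
orientation. Each iteration proposes ``n_candidates`` random steps (uniform
turning angle, gamma step length), extracts and standardizes their
covariates, scores them with the fitted model, and samples one step by its
within-stratum probability — an "inverted" step-selection function.
Candidates that would leave the buffer-expanded grid are redrawn
individually, which keeps dispersers inside the expanded study area.

Because the grid extent is convex and every step is a straight segment, a
candidate whose endpoint lies inside the grid lies entirely inside it, so
endpoint checks suffice for containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .exceptions import OutOfBoundsError, SimulationError
from .issf import (
    GammaStepLength,
    MovementModel,
    apply_standardization,
    design_matrix,
    is_low_activity,
)
from .landscape import CovariateStack, extract_along_segments

_FIX_INTERVAL = pd.Timedelta(hours=4)
_START_HOURS = (0, 4, 8, 12, 16, 20)


@dataclass(frozen=True)
class SourcePoint:
    """Release location of a virtual disperser."""

    x: float
    y: float
    origin: str = "buffer"


@dataclass
class SimulationConfig:
    """Knobs of the dispersal simulation."""

    n_candidates: int = 25
    n_steps: int = 2000
    resample_cap: int = 10_000
    seed: int = 0
    start_time: pd.Timestamp | None = None
    spacing: float | None = None

    def __post_init__(self) -> None:
        if self.n_candidates < 1 or self.n_steps < 1 or self.resample_cap < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class Trajectory:
    """One simulated disperser: positions (n_steps + 1, 2) and headings."""

    source: SourcePoint
    positions: np.ndarray
    headings: np.ndarray
    t0: pd.Timestamp

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    def truncated(self, n_steps: int) -> "Trajectory":
        """First ``n_steps`` steps of the trajectory."""
        n = min(n_steps, self.n_steps)
        return Trajectory(
            source=self.source,
            positions=self.positions[: n + 1],
            headings=self.headings[:n],
            t0=self.t0,
        )


@dataclass
class EnsembleResult:
    trajectories: list[Trajectory]
    boundary_fraction: float


@dataclass
class CheckpointDiagnostic:
    """Prediction-interval widths of checkpoint traversal frequencies.

    ``widths`` is indexed by subsample size m with one column per checkpoint;
    ``converged_at`` is the smallest m at which every checkpoint's 95%
    prediction interval is narrower than the threshold (None if never).
    """

    checkpoints: pd.DataFrame
    widths: pd.DataFrame
    threshold: float
    converged_at: int | None


# ---------------------------------------------------------------------------
# Source points


def place_source_points(
    patches: pd.DataFrame,
    stack: CovariateStack,
    n_patch: int,
    n_buffer: int,
    min_area_km2: float = 700.0,
    rng: np.random.Generator | None = None,
) -> list[SourcePoint]:
    """Release points: uniform over eligible patches and over the buffer ring.

    Patches smaller than ``min_area_km2`` are excluded; points are allocated
    across eligible patches in proportion to area (uniform over the union).
    Buffer points are uniform over the expanded extent minus the core.
    """
    rng = np.random.default_rng(rng)
    out: list[SourcePoint] = []
    if n_patch > 0:
        eligible = [
            (str(row["id"]), row["geometry"])
            for _, row in patches.iterrows()
            if row["geometry"].area / 1e6 >= min_area_km2
        ]
        if not eligible:
            raise ValueError(f"no patch reaches {min_area_km2} km^2")
        areas = np.array([geom.area for _, geom in eligible])
        choice = rng.choice(len(eligible), size=n_patch, p=areas / areas.sum())
        for k in range(len(eligible)):
            pid, geom = eligible[k]
            need = int((choice == k).sum())
            if need == 0:
                continue
            xmin, ymin, xmax, ymax = geom.bounds
            shapely.prepare(geom)
            got = 0
            while got < need:
                batch = max(16, 2 * (need - got))
                x = rng.uniform(xmin, xmax, size=batch)
                y = rng.uniform(ymin, ymax, size=batch)
                ok = shapely.contains_xy(geom, x, y)
                for xi, yi in zip(x[ok], y[ok]):
                    if got == need:
                        break
                    out.append(SourcePoint(x=float(xi), y=float(yi), origin=pid))
                    got += 1
    if n_buffer > 0:
        if stack.buffer_width <= 0:
            raise ValueError("stack has no buffer zone to place buffer points in")
        xmin, ymin, xmax, ymax = stack.grid.extent
        cxmin, cymin, cxmax, cymax = stack.core_extent
        for _ in range(n_buffer):
            while True:
                x = rng.uniform(xmin, xmax)
                y = rng.uniform(ymin, ymax)
                if not (cxmin <= x < cxmax and cymin < y <= cymax):
                    out.append(SourcePoint(x=x, y=y, origin="buffer"))
                    break
    return out


# ---------------------------------------------------------------------------
# Candidate proposal and the simulation loop


def propose_candidates(
    pos,
    heading: float,
    model: MovementModel,
    stack: CovariateStack,
    rng: np.random.Generator,
    n_candidates: int = 25,
    cap: int = 10_000,
    low_activity: int = 0,
    spacing: float | None = None,
):
    """Propose standardized candidate steps from ``pos``.

    Returns ``(frame, n_redrawn)`` where the frame holds raw endpoints and
    headings plus covariates on the model's standardized scale. Candidates
    leaving the grid are redrawn individually up to ``cap`` attempts each.
    """
    grid = stack.grid
    x, y = float(pos[0]), float(pos[1])
    if not grid.contains(x, y):
        raise OutOfBoundsError(f"position ({x}, {y}) outside the (buffered) grid")
    if model.gamma is None:
        raise ValueError("model has no gamma step-length distribution")
    k, theta = model.gamma.k, model.gamma.theta
    ta = rng.uniform(-np.pi, np.pi, size=n_candidates)
    sl = np.maximum(rng.gamma(k, theta, size=n_candidates), 1e-9)
    head = heading + ta
    ex = x + sl * np.cos(head)
    ey = y + sl * np.sin(head)
    inside = grid.contains(ex, ey)
    n_redrawn = 0
    attempts = np.zeros(n_candidates, dtype=np.int64)
    while not inside.all():
        bad = np.flatnonzero(~inside)
        attempts[bad] += 1
        if attempts.max() > cap:
            raise SimulationError(
                f"candidate resampling cap ({cap}) exceeded at position ({x:.1f}, {y:.1f})"
            )
        n_redrawn += bad.size
        ta[bad] = rng.uniform(-np.pi, np.pi, size=bad.size)
        sl[bad] = np.maximum(rng.gamma(k, theta, size=bad.size), 1e-9)
        head[bad] = heading + ta[bad]
        ex[bad] = x + sl[bad] * np.cos(head[bad])
        ey[bad] = y + sl[bad] * np.sin(head[bad])
        inside = grid.contains(ex, ey)
    frame = {
        "x_end": ex,
        "y_end": ey,
        "heading": head,
        "sl": sl,
        "log_sl": np.log(sl),
        "cos_ta": np.cos(ta),
        "low_activity": np.full(n_candidates, float(low_activity)),
    }
    habitat = extract_along_segments(
        stack,
        np.full(n_candidates, x),
        np.full(n_candidates, y),
        ex,
        ey,
        spacing=spacing,
    )
    frame.update(habitat)
    frame = apply_standardization(frame, model.standardization)
    return frame, n_redrawn


def sample_candidate(rng: np.random.Generator, p: np.ndarray) -> int:
    """Draw one candidate index by its within-stratum probability."""
    return int(rng.choice(len(p), p=p))


def _softmax(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.max()
    w = np.exp(eta)
    return w / w.sum()


def simulate_trajectory(
    source: SourcePoint,
    model: MovementModel,
    stack: CovariateStack,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one disperser for ``config.n_steps`` steps."""
    x, y = float(source.x), float(source.y)
    if not stack.grid.contains(x, y):
        raise OutOfBoundsError(f"source ({x}, {y}) outside the (buffered) grid")
    heading = rng.uniform(-np.pi, np.pi)
    if config.start_time is None:
        t = pd.Timestamp("2000-01-01") + pd.Timedelta(
            hours=int(rng.choice(_START_HOURS))
        )
    else:
        t = pd.Timestamp(config.start_time)
    n = config.n_steps
    positions = np.empty((n + 1, 2))
    headings = np.empty(n)
    positions[0] = (x, y)
    t0 = t
    beta = model.beta
    for step in range(n):
        frame, _ = propose_candidates(
            (x, y),
            heading,
            model,
            stack,
            rng,
            n_candidates=config.n_candidates,
            cap=config.resample_cap,
            low_activity=is_low_activity(t),
            spacing=config.spacing,
        )
        X = design_matrix(frame, model.terms)
        p = _softmax(X @ beta)
        pick = sample_candidate(rng, p)
        x = float(frame["x_end"][pick])
        y = float(frame["y_end"][pick])
        heading = float(frame["heading"][pick])
        positions[step + 1] = (x, y)
        headings[step] = heading
        t = t + _FIX_INTERVAL
    return Trajectory(source=source, positions=positions, headings=headings, t0=t0)


def simulate_ensemble(
    sources: Sequence[SourcePoint],
    model: MovementModel,
    stack: CovariateStack,
    config: SimulationConfig,
) -> EnsembleResult:
    """One trajectory per source point, reproducible and order-independent.

    Each trajectory runs on its own random substream spawned from the master
    seed, so results do not depend on execution order. The fraction of
    trajectories that leave the core study area at least once is reported.
    """
    if len(sources) == 0:
        raise ValueError("sources is empty")
    streams = np.random.SeedSequence(config.seed).spawn(len(sources))
    trajectories = []
    n_boundary = 0
    cxmin, cymin, cxmax, cymax = stack.core_extent
    for source, ss in zip(sources, streams):
        traj = simulate_trajectory(source, model, stack, config, np.random.default_rng(ss))
        trajectories.append(traj)
        xs, ys = traj.positions[:, 0], traj.positions[:, 1]
        outside = (xs < cxmin) | (xs >= cxmax) | (ys <= cymin) | (ys > cymax)
        if outside.any():
            n_boundary += 1
    return EnsembleResult(
        trajectories=trajectories,
        boundary_fraction=n_boundary / len(sources),
    )


# ---------------------------------------------------------------------------
# Steady-state diagnostic


def _checkpoint_hits(trajectories, checkpoints: pd.DataFrame) -> np.ndarray:
    """(n_traj, n_checkpoints) bool: does any position fall in the rectangle."""
    xmin = checkpoints["xmin"].to_numpy()
    ymin = checkpoints["ymin"].to_numpy()
    xmax = checkpoints["xmax"].to_numpy()
    ymax = checkpoints["ymax"].to_numpy()
    out = np.zeros((len(trajectories), len(checkpoints)), dtype=bool)
    for r, traj in enumerate(trajectories):
        xs = traj.positions[:, 0][:, None]
        ys = traj.positions[:, 1][:, None]
        hit = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
        out[r] = hit.any(axis=0)
    return out


def convergence_diagnostic(
    trajectories: Sequence[Trajectory],
    core_extent: Sequence[float],
    n_checkpoints: int = 1000,
    size: float = 5000.0,
    sizes: Sequence[int] | None = None,
    reps: int = 100,
    threshold: float = 0.01,
    rng: np.random.Generator | None = None,
) -> CheckpointDiagnostic:
    """Checkpoint-based steady-state diagnostic.

    Rectangular checkpoints (``size`` x ``size`` m) are scattered uniformly in
    the core extent. For each subsample size m, ``reps`` subsets of
    trajectories are drawn without replacement; the relative traversal
    frequency of each checkpoint (fraction of subset trajectories
    intersecting it) is computed per subset, and the 95% prediction-interval
    width per checkpoint is recorded. The ensemble is converged at the
    smallest m whose widths all fall below ``threshold``.
    """
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    rng = np.random.default_rng(rng)
    xmin, ymin, xmax, ymax = core_extent
    if xmax - xmin < size or ymax - ymin < size:
        raise ValueError("core extent smaller than the checkpoint size")
    cx = rng.uniform(xmin, xmax - size, size=n_checkpoints)
    cy = rng.uniform(ymin, ymax - size, size=n_checkpoints)
    checkpoints = pd.DataFrame(
        {"xmin": cx, "ymin": cy, "xmax": cx + size, "ymax": cy + size}
    )
    hits = _checkpoint_hits(trajectories, checkpoints)
    n = len(trajectories)
    if sizes is None:
        sizes = [m for m in (10, 30, 100, 300, 1000, 3000, 10_000) if m <= n]
        if n not in sizes:
            sizes.append(n)
    rows = {}
    for m in sizes:
        if m > n:
            import warnings

            warnings.warn(f"subsample size {m} exceeds ensemble size {n}; skipped")
            continue
        freqs = np.empty((reps, n_checkpoints))
        for r in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            freqs[r] = hits[idx].mean(axis=0)
        lo = np.percentile(freqs, 2.5, axis=0)
        hi = np.percentile(freqs, 97.5, axis=0)
        rows[m] = hi - lo
    widths = pd.DataFrame.from_dict(rows, orient="index")
    widths.index.name = "m"
    converged_at = None
    for m in sorted(rows):
        if np.all(rows[m] < threshold):
            converged_at = int(m)
            break
    return CheckpointDiagnostic(
        checkpoints=checkpoints,
        widths=widths,
        threshold=threshold,
        converged_at=converged_at,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format table (trajectory, step, x, y, t) for CSV export."""
    parts = []
    for k, traj in enumerate(trajectories):
        n = len(traj.positions)
        parts.append(
            pd.DataFrame(
                {
                    "trajectory": k,
                    "step": np.arange(n),
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                    "t": traj.t0 + _FIX_INTERVAL * np.arange(n),
                    "origin": traj.source.origin,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(frame: pd.DataFrame) -> list[Trajectory]:
    """Rebuild trajectories from the long-format table."""
    out = []
    for _, grp in frame.groupby("trajectory", sort=True):
        grp = grp.sort_values("step")
        pos = grp[["x", "y"]].to_numpy(dtype=float)
        d = np.diff(pos, axis=0)
        origin = str(grp["origin"].iloc[0]) if "origin" in grp.columns else "buffer"
        out.append(
            Trajectory(
                source=SourcePoint(x=pos[0, 0], y=pos[0, 1], origin=origin),
                positions=pos,
                headings=np.arctan2(d[:, 1], d[:, 0]),
                t0=pd.Timestamp(grp["t"].iloc[0]) if "t" in grp.columns else pd.Timestamp("2000-01-01"),
            )
        )
    return out
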