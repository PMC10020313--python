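"""Path-selection-function (PSF) validation of a connectivity surface.

Each observed dispersal path is contrasted with rigid-motion replicates of
itself: the path is rotated by a random angle about its first vertex and
shifted by a random distance in a random direction, which preserves its
shape (inter-vertex distances and turn angles) exactly. The mean surface
value over the cells each path traverses enters a one-covariate conditional
logistic regression; a positive coefficient means observed paths follow
high-connectivity areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import Heatmap
from .issf import fit_clogit
from .landscape import cells_traversed

logger = logging.getLogger(__name__)


@dataclass
class PSFResult:
    coefficient: float
    se: float
    z: float
    n_strata: int
    n_dropped: int


def random_paths(
    path: np.ndarray,
    n: int,
    d_max: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Rigid-motion null paths: rotate about the first vertex, then shift.

    Rotation angle ~ U(-pi, pi); shift distance ~ U(0, d_max) in a direction
    ~ U(-pi, pi). Path shape is preserved exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    path = np.asarray(path, dtype=float)
    pivot = path[0]
    rel = path - pivot
    out = []
    for _ in range(n):
        alpha = rng.uniform(-np.pi, np.pi)
        d = rng.uniform(0.0, d_max)
        phi = rng.uniform(-np.pi, np.pi)
        c, s = np.cos(alpha), np.sin(alpha)
        rot = rel @ np.array([[c, s], [-s, c]])
        shift = pivot + d * np.array([np.cos(phi), np.sin(phi)])
        out.append(rot + shift)
    return out


def path_connectivity(surface: Heatmap, path: np.ndarray) -> float:
    """Mean surface value over the set of cells the path traverses.

    Cells outside the surface grid contribute nothing; NaN when the path
    does not overlap the grid at all.
    """
    path = np.asarray(path, dtype=float)
    cells: set[tuple[int, int]] = set()
    for a in range(len(path) - 1):
        cells.update(cells_traversed(surface.grid, path[a], path[a + 1], clip=True))
    if len(path) == 1:
        cells.update(cells_traversed(surface.grid, path[0], path[0], clip=True))
    if not cells:
        return float("nan")
    ii, jj = zip(*cells)
    values = surface.counts[list(ii), list(jj)].astype(float)
    values = values[np.isfinite(values)]
    return float(values.mean()) if values.size else float("nan")


def build_path_strata(
    paths: Sequence[np.ndarray],
    surface: Heatmap,
    n_random: int = 50,
    d_max: float = 50_000.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed-vs-null strata with the connectivity covariate attached.

    Null paths that do not overlap the surface are dropped from their
    stratum; strata whose observed path has no overlap (or with no remaining
    null) are dropped entirely, with a log message.
    """
    rng = np.random.default_rng(rng)
    rows = []
    n_dropped = 0
    for s, path in enumerate(paths):
        obs = path_connectivity(surface, path)
        if not np.isfinite(obs):
            n_dropped += 1
            continue
        nulls = [
            path_connectivity(surface, rp)
            for rp in random_paths(path, n_random, d_max, rng)
        ]
        nulls = [v for v in nulls if np.isfinite(v)]
        if not nulls:
            n_dropped += 1
            continue
        rows.append({"stratum": s, "case": 1, "connectivity": obs})
        rows.extend({"stratum": s, "case": 0, "connectivity": v} for v in nulls)
    if n_dropped:
        logger.info("build_path_strata dropped %d strata without surface overlap", n_dropped)
    frame = pd.DataFrame(rows)
    frame.attrs["n_dropped"] = n_dropped
    return frame


def psf_fit(strata: pd.DataFrame) -> PSFResult:
    """One-covariate conditional logistic fit of observed vs null paths."""
    if strata["stratum"].nunique() < 2:
        raise ValueError("need at least 2 usable path strata")
    model = fit_clogit(strata, ["connectivity"])
    se = float(model.se().iloc[0])
    coef = float(model.beta[0])
    return PSFResult(
        coefficient=coef,
        se=se,
        z=coef / se,
        n_strata=int(strata["stratum"].nunique()),
        n_dropped=int(strata.attrs.get("n_dropped", 0)),
    )


def validate_surface(
    paths: Sequence[np.ndarray],
    surface: Heatmap,
    n_random: int = 50,
    d_max: float = 50_000.0,
    rng: np.random.Generator | None = None,
) -> PSFResult:
    """Convenience wrapper: build path strata and fit the PSF."""
    strata = build_path_strata(paths, surface, n_random=n_random, d_max=d_max, rng=rng)
    return psf_fit(strata)
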