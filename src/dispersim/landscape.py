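"""Raster data model for habitat covariates.

All coordinates are projected meters. A :class:`GridSpec` describes a regular
north-up grid whose cell ``(row i, col j)`` covers the half-open square
``[x0 + j*res, x0 + (j+1)*res)`` in x and ``(y0 - (i+1)*res, y0 - i*res]`` in
y, so every point maps to exactly one cell even on cell boundaries. A
:class:`CovariateStack` bundles several named layers on one grid and can be
expanded by a randomized buffer zone that absorbs boundary effects during
simulation.

GeoTIFF files are read and written through :mod:`tifffile` using the two
standard georeferencing tags (ModelPixelScale and ModelTiepoint); no CRS
handling is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .exceptions import AlignmentError, MissingDataError, OutOfBoundsError

_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (projected meters, north-up)."""

    x0: float
    y0: float
    res: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError("res must be > 0")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("ncols and nrows must be >= 1")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.x0,
            self.y0 - self.nrows * self.res,
            self.x0 + self.ncols * self.res,
            self.y0,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def contains(self, x, y):
        """Whether points lie inside the grid (half-open cell convention)."""
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_of(self, x, y):
        """Map point(s) to (row, col) indices.  No bounds check."""
        j = np.floor((np.asarray(x, dtype=float) - self.x0) / self.res).astype(np.int64)
        i = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.res).astype(np.int64)
        return i, j

    def cell_center(self, i, j):
        x = self.x0 + (np.asarray(j) + 0.5) * self.res
        y = self.y0 - (np.asarray(i) + 0.5) * self.res
        return x, y

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid with the same origin and ``factor``-times larger cells."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return GridSpec(
            x0=self.x0,
            y0=self.y0,
            res=self.res * factor,
            ncols=math.ceil(self.ncols / factor),
            nrows=math.ceil(self.nrows / factor),
        )


def grid_from_extent(extent: Sequence[float], res: float) -> GridSpec:
    """Smallest grid with cell size ``res`` covering ``(xmin, ymin, xmax, ymax)``."""
    xmin, ymin, xmax, ymax = extent
    return GridSpec(
        x0=xmin,
        y0=ymax,
        res=res,
        ncols=max(1, math.ceil((xmax - xmin) / res)),
        nrows=max(1, math.ceil((ymax - ymin) / res)),
    )


@dataclass
class CovariateStack:
    """Named covariate layers sharing one grid.

    ``buffer_width`` is 0 for an unexpanded stack; after
    :func:`expand_with_buffer` the original study-area rectangle is kept in
    ``core_extent`` so core cells can be recovered exactly.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    buffer_width: float = 0.0
    core_extent: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise AlignmentError(
                    f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
                )
            self.layers[name] = arr
        if self.core_extent is None:
            self.core_extent = self.grid.extent

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            buffer_width=self.buffer_width,
            core_extent=self.core_extent,
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(path, grid: GridSpec, values: np.ndarray) -> None:
    """Write one layer as a single-band GeoTIFF (float64, NaN = missing)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise AlignmentError(f"array shape {values.shape} != grid shape {grid.shape}")
    extratags = [
        (_TAG_PIXELSCALE, "d", 3, (float(grid.res), float(grid.res), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.x0), float(grid.y0), 0.0), True),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def read_raster(path) -> tuple[GridSpec, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        try:
            sx, sy, _ = page.tags[_TAG_PIXELSCALE].value
            tie = page.tags[_TAG_TIEPOINT].value
        except KeyError as exc:  # pragma: no cover - malformed input
            raise AlignmentError(f"{path}: missing GeoTIFF georeferencing tags") from exc
    if not math.isclose(sx, sy):
        raise AlignmentError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    nrows, ncols = values.shape
    grid = GridSpec(x0=float(tie[3]), y0=float(tie[4]), res=float(sx), ncols=ncols, nrows=nrows)
    return grid, values


def read_stack(paths: Mapping[str, str | Path]) -> CovariateStack:
    """Load aligned GeoTIFF layers into a stack, in declared order."""
    grid = None
    layers: dict[str, np.ndarray] = {}
    for name, path in paths.items():
        g, values = read_raster(path)
        if grid is None:
            grid = g
        elif g != grid:
            raise AlignmentError(f"layer {name!r} grid {g} does not match {grid}")
        layers[name] = values
    if grid is None:
        raise ValueError("no layers given")
    return CovariateStack(grid=grid, layers=layers)


def write_stack(stack: CovariateStack, directory, manifest: str | None = "stack.yml") -> dict[str, Path]:
    """Write each layer as ``<name>.tif`` plus an optional YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, values in stack.layers.items():
        p = directory / f"{name}.tif"
        write_raster(p, stack.grid, values)
        paths[name] = p
    if manifest:
        doc = {"layers": {name: p.name for name, p in paths.items()}}
        (directory / manifest).write_text(yaml.safe_dump(doc, sort_keys=False))
    return paths


def read_manifest(path) -> CovariateStack:
    """Read a stack from a YAML/JSON manifest mapping layer names to files."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    layers = doc["layers"] if "layers" in doc else doc
    return read_stack({name: path.parent / p for name, p in layers.items()})


# ---------------------------------------------------------------------------
# Buffer expansion


def expand_with_buffer(stack: CovariateStack, width: float, seed) -> CovariateStack:
    """Enlarge the grid by a randomized buffer zone of ``width`` meters.

    Buffer cells of each layer are filled by sampling with replacement
    (i.i.d. per cell) from that layer's non-missing core cells; core cells
    are unchanged. ``width`` is rounded up to whole cells.
    """
    if width < 0:
        raise ValueError("buffer width must be >= 0")
    if stack.buffer_width > 0:
        raise ValueError("stack is already buffer-expanded")
    if width == 0:
        return stack.copy()
    rng = np.random.default_rng(seed)
    grid = stack.grid
    b = math.ceil(width / grid.res)
    new_grid = GridSpec(
        x0=grid.x0 - b * grid.res,
        y0=grid.y0 + b * grid.res,
        res=grid.res,
        ncols=grid.ncols + 2 * b,
        nrows=grid.nrows + 2 * b,
    )
    core = (slice(b, b + grid.nrows), slice(b, b + grid.ncols))
    buffer_mask = np.ones(new_grid.shape, dtype=bool)
    buffer_mask[core] = False
    n_buffer = int(buffer_mask.sum())
    layers = {}
    for name, values in stack.layers.items():
        pool = values[np.isfinite(values)]
        if pool.size == 0:
            raise MissingDataError(f"layer {name!r} has no non-missing cells to resample")
        out = np.empty(new_grid.shape, dtype=float)
        out[core] = values
        out[buffer_mask] = rng.choice(pool, size=n_buffer, replace=True)
        layers[name] = out
    return CovariateStack(
        grid=new_grid,
        layers=layers,
        buffer_width=b * grid.res,
        core_extent=grid.extent,
    )


def crop_to_core(stack: CovariateStack) -> CovariateStack:
    """Inverse of :func:`expand_with_buffer` on the core cells."""
    if stack.buffer_width == 0:
        return stack.copy()
    b = round(stack.buffer_width / stack.grid.res)
    grid = GridSpec(
        x0=stack.grid.x0 + b * stack.grid.res,
        y0=stack.grid.y0 - b * stack.grid.res,
        res=stack.grid.res,
        ncols=stack.grid.ncols - 2 * b,
        nrows=stack.grid.nrows - 2 * b,
    )
    core = (slice(b, b + grid.nrows), slice(b, b + grid.ncols))
    return CovariateStack(
        grid=grid,
        layers={k: v[core].copy() for k, v in stack.layers.items()},
    )


# ---------------------------------------------------------------------------
# Segment traversal and extraction


def _clip_segment(grid: GridSpec, p0, p1):
    """Clip segment to the grid extent; None if no overlap (Liang-Barsky)."""
    xmin, ymin, xmax, ymax = grid.extent
    eps = grid.res * 1e-9
    # Treat the extent as the closed box shrunk so that clipped points map to
    # valid cells under the half-open convention.
    xmax -= eps
    ymin += eps
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - xmin),
        (dx, xmax - x0),
        (-dy, y0 - ymin),
        (dy, ymax - y0),
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            if t > t1:
                return None
            t0 = max(t0, t)
        else:
            if t < t0:
                return None
            t1 = min(t1, t)
    if t0 > t1:
        return None
    return (x0 + t0 * dx, y0 + t0 * dy), (x0 + t1 * dx, y0 + t1 * dy)


def cells_traversed(grid: GridSpec, p0, p1, clip: bool = False):
    """Ordered, duplicate-free cells whose squares the segment intersects.

    With ``clip=True`` the segment is first clipped to the grid extent and an
    empty list is returned when it does not overlap the grid; otherwise both
    endpoints must lie inside the grid.
    """
    if clip:
        clipped = _clip_segment(grid, p0, p1)
        if clipped is None:
            return []
        p0, p1 = clipped
    elif not (grid.contains(*p0) and grid.contains(*p1)):
        raise OutOfBoundsError(f"segment {p0}->{p1} leaves the grid extent {grid.extent}")
    x0, y0 = p0
    x1, y1 = p1
    if x0 == x1 and y0 == y1:
        i, j = grid.cell_of(x0, y0)
        return [(int(i), int(j))]
    dx, dy = x1 - x0, y1 - y0
    ts = [0.0, 1.0]
    if dx != 0.0:
        xa, xb = (x0, x1) if x0 < x1 else (x1, x0)
        ja = math.ceil((xa - grid.x0) / grid.res)
        jb = math.floor((xb - grid.x0) / grid.res)
        for j in range(ja, jb + 1):
            t = (grid.x0 + j * grid.res - x0) / dx
            if 0.0 < t < 1.0:
                ts.append(t)
    if dy != 0.0:
        ya, yb = (y0, y1) if y0 < y1 else (y1, y0)
        ia = math.ceil((grid.y0 - yb) / grid.res)
        ib = math.floor((grid.y0 - ya) / grid.res)
        for i in range(ia, ib + 1):
            t = ((grid.y0 - i * grid.res) - y0) / dy
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(np.asarray(ts))
    mids = 0.5 * (ts[:-1] + ts[1:])
    ii, jj = grid.cell_of(x0 + mids * dx, y0 + mids * dy)
    out: list[tuple[int, int]] = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        if not out or out[-1] != (i, j):
            out.append((i, j))
    return out


def extract_along_segments(
    stack: CovariateStack,
    x0,
    y0,
    x1,
    y1,
    spacing: float | None = None,
):
    """Vectorized along-segment covariate averages for many segments.

    Points are placed evenly from each segment's start to its end inclusive,
    with inter-point distance at most ``spacing`` (default half a cell); the
    unweighted mean of non-missing layer values at those points is returned
    per layer. Degenerate segments use a single point. Segments whose sample
    points all fall on missing cells yield NaN.
    """
    grid = stack.grid
    if spacing is None:
        spacing = grid.res / 2.0
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    m = x0.size
    length = np.hypot(x1 - x0, y1 - y0)
    n_pts = np.maximum(2, np.ceil(length / spacing).astype(np.int64) + 1)
    n_pts[length == 0.0] = 1
    starts = np.concatenate(([0], np.cumsum(n_pts)[:-1]))
    total = int(n_pts.sum())
    seg = np.repeat(np.arange(m), n_pts)
    local = np.arange(total) - starts[seg]
    denom = np.maximum(n_pts - 1, 1)
    t = local / denom[seg]
    px = x0[seg] + t * (x1 - x0)[seg]
    py = y0[seg] + t * (y1 - y0)[seg]
    inside = grid.contains(px, py)
    if not inside.all():
        bad = seg[~inside][0]
        raise OutOfBoundsError(
            f"segment {bad} ({x0[bad]:.1f},{y0[bad]:.1f})->({x1[bad]:.1f},{y1[bad]:.1f}) "
            "leaves the grid extent"
        )
    i, j = grid.cell_of(px, py)
    out: dict[str, np.ndarray] = {}
    for name, values in stack.layers.items():
        v = values[i, j]
        ok = np.isfinite(v)
        sums = np.add.reduceat(np.where(ok, v, 0.0), starts)
        cnts = np.add.reduceat(ok.astype(np.int64), starts)
        with np.errstate(invalid="ignore"):
            out[name] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return out


def extract_along_segment(stack: CovariateStack, p0, p1, spacing: float | None = None):
    """Along-segment covariate average for a single segment (see plural form)."""
    res = extract_along_segments(
        stack, [p0[0]], [p0[1]], [p1[0]], [p1[1]], spacing=spacing
    )
    out = {}
    for name, arr in res.items():
        v = float(arr[0])
        if not np.isfinite(v):
            raise MissingDataError(f"all sampled values of layer {name!r} are missing")
        out[name] = v
    return out
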