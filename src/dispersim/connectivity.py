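"""Step 3: connectivity maps derived from simulated trajectories.

Three complementary products:

* **Heatmap** — how many *distinct* trajectories traverse each raster cell
  (a trajectory looping through a cell repeatedly still counts once).
* **Betweenness map** — trajectories are coarsened to a transition network
  whose nodes are cell centers and whose directed edges carry the frequency
  of observed cell-to-cell transitions; edge costs invert the frequency
  (omega = mean frequency / frequency) so heavily used edges are cheap, and
  weighted node betweenness highlights corridors and bottlenecks.
* **Inter-patch connectivity** — per ordered patch pair, the fraction of
  dispersers from the source patch whose trajectory enters the target patch
  at least once, and the mean number of steps to first arrival.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import shapely

from .landscape import GridSpec, cells_traversed
from .simulator import Trajectory


@dataclass
class Heatmap:
    """Per-cell count of distinct traversing trajectories."""

    grid: GridSpec
    counts: np.ndarray
    n_trajectories: int = 0


@dataclass
class TransitionNetwork:
    """Directed cell-to-cell transition network.

    ``edges`` columns: from_i, from_j, to_i, to_j, frequency, weight, where
    weight = mean(frequency) / frequency (an average-frequency edge costs 1).
    ``nodes`` lists every visited cell, including isolated ones.
    """

    grid: GridSpec
    nodes: pd.DataFrame
    edges: pd.DataFrame

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for _, row in self.nodes.iterrows():
            g.add_node((int(row["i"]), int(row["j"])))
        for _, row in self.edges.iterrows():
            g.add_edge(
                (int(row["from_i"]), int(row["from_j"])),
                (int(row["to_i"]), int(row["to_j"])),
                frequency=float(row["frequency"]),
                weight=float(row["weight"]),
            )
        return g


@dataclass
class BetweennessMap:
    """Node betweenness mapped back to the raster (NaN off-network)."""

    grid: GridSpec
    scores: np.ndarray
    node_scores: pd.DataFrame


def heatmap(trajectories: Sequence[Trajectory], grid: GridSpec) -> Heatmap:
    """Rasterize trajectories, counting each trajectory once per cell.

    Segments are traced with a supercover traversal and clipped to the grid,
    so cells are counted even when a step only passes through them.
    """
    counts = np.zeros(grid.shape, dtype=np.int64)
    for traj in trajectories:
        cells: set[tuple[int, int]] = set()
        pos = traj.positions
        for a in range(len(pos) - 1):
            cells.update(cells_traversed(grid, pos[a], pos[a + 1], clip=True))
        if cells:
            ii, jj = zip(*cells)
            counts[list(ii), list(jj)] += 1
    return Heatmap(grid=grid, counts=counts, n_trajectories=len(trajectories))


def build_network(
    trajectories: Sequence[Trajectory],
    grid: GridSpec,
    supercover: bool = False,
) -> TransitionNetwork:
    """Aggregate directed cell-to-cell transitions over all trajectories.

    By default transitions link the cells of consecutive step *endpoints*
    (self-transitions dropped); with ``supercover=True`` each step is routed
    through the full sequence of cells its segment crosses.
    """
    trans: Counter[tuple[tuple[int, int], tuple[int, int]]] = Counter()
    visited: set[tuple[int, int]] = set()
    for traj in trajectories:
        pos = traj.positions
        if supercover:
            cells: list[tuple[int, int]] = []
            for a in range(len(pos) - 1):
                seg = cells_traversed(grid, pos[a], pos[a + 1], clip=True)
                if cells and seg and cells[-1] == seg[0]:
                    seg = seg[1:]
                cells.extend(seg)
        else:
            ii, jj = grid.cell_of(pos[:, 0], pos[:, 1])
            cells = list(zip(ii.tolist(), jj.tolist()))
        visited.update(cells)
        for a, b in zip(cells[:-1], cells[1:]):
            if a != b:
                trans[(a, b)] += 1
    if trans:
        freq = np.array(list(trans.values()), dtype=float)
        weight = freq.mean() / freq
        pairs = list(trans.keys())
        edges = pd.DataFrame(
            {
                "from_i": [a[0] for a, _ in pairs],
                "from_j": [a[1] for a, _ in pairs],
                "to_i": [b[0] for _, b in pairs],
                "to_j": [b[1] for _, b in pairs],
                "frequency": freq.astype(int),
                "weight": weight,
            }
        )
    else:
        edges = pd.DataFrame(
            columns=["from_i", "from_j", "to_i", "to_j", "frequency", "weight"]
        )
    nodes = pd.DataFrame(sorted(visited), columns=["i", "j"])
    return TransitionNetwork(grid=grid, nodes=nodes, edges=edges)


def betweenness(network: TransitionNetwork) -> BetweennessMap:
    """Weighted directed node betweenness (Brandes/Dijkstra, omega as cost).

    Equal-cost shortest paths share credit fractionally; scores of cells not
    in the network are NaN on the raster.
    """
    if len(network.nodes) == 0:
        raise ValueError("network is empty")
    if len(network.edges) and (network.edges["weight"] <= 0).any():
        raise ValueError("edge weights must be > 0")
    g = network.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False, weight="weight")
    scores = np.full(network.grid.shape, np.nan)
    rows = []
    for (i, j), score in bc.items():
        rows.append({"i": i, "j": j, "betweenness": score})
        if 0 <= i < network.grid.nrows and 0 <= j < network.grid.ncols:
            scores[i, j] = score
    return BetweennessMap(
        grid=network.grid,
        scores=scores,
        node_scores=pd.DataFrame(rows).sort_values(["i", "j"]).reset_index(drop=True),
    )


def interpatch(
    trajectories: Sequence[Trajectory], patches: pd.DataFrame
) -> pd.DataFrame:
    """Inter-patch connectivity table over ordered patch pairs.

    A trajectory from source patch s succeeds for target t when any of its
    positions lies inside t; the first such step index enters the dispersal
    duration. Trajectories originating in the buffer are not origins.
    Columns: source, target, n_origin, n_success, fraction, mean_steps.
    """
    if len(patches) == 0:
        raise ValueError("empty patch set")
    ids = [str(pid) for pid in patches["id"]]
    geoms = list(patches["geometry"])
    for geom in geoms:
        shapely.prepare(geom)
    origins = [str(t.source.origin) for t in trajectories]
    n_origin = Counter(o for o in origins if o in set(ids))
    first_arrival: dict[tuple[str, str], list[int]] = {}
    for traj, origin in zip(trajectories, origins):
        if origin not in n_origin:
            continue
        xs, ys = traj.positions[:, 0], traj.positions[:, 1]
        for pid, geom in zip(ids, geoms):
            if pid == origin:
                continue
            inside = shapely.contains_xy(geom, xs, ys)
            if inside.any():
                first_arrival.setdefault((origin, pid), []).append(
                    int(np.flatnonzero(inside)[0])
                )
    rows = []
    for s in ids:
        if n_origin.get(s, 0) == 0:
            continue
        for t in ids:
            if t == s:
                continue
            steps = first_arrival.get((s, t), [])
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "n_origin": n_origin[s],
                    "n_success": len(steps),
                    "fraction": len(steps) / n_origin[s],
                    "mean_steps": float(np.mean(steps)) if steps else np.nan,
                }
            )
    return pd.DataFrame(rows)
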